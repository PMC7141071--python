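"""Directional and fluctuating asymmetry decomposition.

The core is the classical two-way mixed-model ANOVA on replicated
measurements of left and right wings (the Palmer–Strobeck scheme):
individuals are a random effect, side a fixed effect whose mean square —
tested over the side x individual interaction — detects directional
asymmetry (DA); the interaction, tested over the replicate error, detects
fluctuating asymmetry (FA) in excess of measurement error. With r
replicates per wing, E[MS_error] = sigma_ME^2 and
E[MS_interaction] = sigma_ME^2 + r sigma_FA^2, so
sigma_FA^2 is estimated as (MS_interaction - MS_error) / r.

Group-level analyses work on the signed per-individual asymmetry
A = R - L (replicate-averaged per side): one-sample DA tests per
population x temperature cell, a fixed-effects ANOVA of A on temperature,
population and their interaction, Levene's test on A for FA-spread
differences, and pairwise comparisons of the temperature-vs-asymmetry
slopes among populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plasticity import (AnovaTable, ModelSpec, fit_linear_model,
                         pairwise_slope_ttest, simple_regression)


@dataclass
class MixedAnovaResult:
    trait: str
    n_individuals: int
    replicates: float
    ss: dict[str, float]          # individual, side, interaction, error
    df: dict[str, int]
    ms: dict[str, float]
    F_DA: float                   # MS_side / MS_interaction
    p_DA: float
    F_FA: float                   # MS_interaction / MS_error
    p_FA: float
    F_individual: float           # MS_individual / MS_interaction
    p_individual: float
    da_estimate: float            # mean(R) - mean(L)
    sigma2_fa: float              # (MS_int - MS_err) / r, floored at 0
    me_fa_ratio: float            # MS_interaction / MS_error
    flags: list[str] = field(default_factory=list)


def _safe_f(ms_num, df_num, ms_den, df_den):
    if not np.isfinite(ms_den) or ms_den <= 0:
        return (np.nan, np.nan) if ms_num == 0 else (np.inf, 0.0)
    F = ms_num / ms_den
    return float(F), float(stats.f.sf(F, df_num, df_den))


def sides_mixed_anova(table: pd.DataFrame, trait: str,
                      group: dict | None = None) -> MixedAnovaResult:
    """Two-way (individual x side) ANOVA with replicated measurements.

    Only complete individuals (both sides present) enter. Balanced designs
    use the exact cell-means decomposition; unbalanced replicate counts fall
    back to sequential SS from the linear-model engine and are flagged.
    Requires r >= 2 replicates — with a single measurement per wing FA
    cannot be separated from measurement error.
    """
    df = table
    if group:
        for k, v in group.items():
            df = df[df[k] == v]
    sides_per_ind = df.groupby("individual_id", observed=True)["side"].nunique()
    complete = sides_per_ind[sides_per_ind == 2].index
    df = df[df["individual_id"].isin(complete)]
    n = len(complete)
    if n < 2:
        raise ValueError("need >= 2 complete individuals")
    rep_counts = df.groupby(["individual_id", "side"], observed=True).size()
    if rep_counts.min() < 2:
        raise ValueError("FA not separable from measurement error: "
                         "need >= 2 replicates per wing")

    flags: list[str] = []
    balanced = rep_counts.nunique() == 1
    if balanced:
        r = int(rep_counts.iloc[0])
        wide = df.pivot_table(index="individual_id", columns=["side", "replicate"],
                              values=trait, observed=True, sort=True)
        arr = wide.to_numpy(float).reshape(n, 2, r)   # columns sorted: L reps, R reps
        cell = arr.mean(axis=2)                        # (n, 2)
        ind_mean = cell.mean(axis=1)
        side_mean = cell.mean(axis=0)
        grand = cell.mean()
        ss_ind = 2 * r * float(((ind_mean - grand) ** 2).sum())
        ss_side = n * r * float(((side_mean - grand) ** 2).sum())
        ss_int = r * float(((cell - ind_mean[:, None] - side_mean[None, :]
                             + grand) ** 2).sum())
        ss_err = float(((arr - cell[:, :, None]) ** 2).sum())
        da = float(side_mean[1] - side_mean[0])        # R minus L (sorted sides)
        r_eff = float(r)
    else:
        flags.append("unbalanced")
        spec = ModelSpec(trait, ["individual_id", "side", "individual_id:side"],
                         factors=("individual_id", "side"))
        tab = fit_linear_model(df, spec).table
        ss_ind = float(tab.loc["individual_id", "ss"])
        ss_side = float(tab.loc["side", "ss"])
        ss_int = float(tab.loc["individual_id:side", "ss"])
        ss_err = float(tab.loc["Residual", "ss"])
        sm = df.groupby(["individual_id", "side"], observed=True)[trait].mean() \
               .groupby("side").mean()
        da = float(sm["R"] - sm["L"])
        r_eff = float(rep_counts.mean())

    dfs = {"individual": n - 1, "side": 1, "interaction": n - 1,
           "error": int(rep_counts.sum()) - 2 * n}
    sss = {"individual": ss_ind, "side": ss_side,
           "interaction": ss_int, "error": ss_err}
    mss = {k: (sss[k] / dfs[k] if dfs[k] > 0 else np.nan) for k in sss}

    F_da, p_da = _safe_f(mss["side"], 1, mss["interaction"], dfs["interaction"])
    F_fa, p_fa = _safe_f(mss["interaction"], dfs["interaction"],
                         mss["error"], dfs["error"])
    F_ind, p_ind = _safe_f(mss["individual"], dfs["individual"],
                           mss["interaction"], dfs["interaction"])
    if mss["interaction"] == 0:
        flags.append("degenerate: zero interaction MS")
    if mss["error"] == 0:
        flags.append("degenerate: zero error MS")
    s2fa = (mss["interaction"] - mss["error"]) / r_eff
    if s2fa < 0:
        flags.append("sigma2_fa floored at 0")
        s2fa = 0.0
    ratio = mss["interaction"] / mss["error"] if mss["error"] > 0 else np.inf
    return MixedAnovaResult(
        trait=trait, n_individuals=n, replicates=r_eff,
        ss=sss, df=dfs, ms=mss,
        F_DA=F_da, p_DA=p_da, F_FA=F_fa, p_FA=p_fa,
        F_individual=F_ind, p_individual=p_ind,
        da_estimate=da, sigma2_fa=float(s2fa), me_fa_ratio=float(ratio),
        flags=flags)


@dataclass
class AsymmetryGroupSummary:
    population: object
    temperature: object
    n: int
    da_mean: float
    fa_sd: float
    statistic: float      # t (one-sample) or F_DA (mixed ANOVA)
    p: float
    method: str
    flags: list[str] = field(default_factory=list)


def da_group_tests(individuals: pd.DataFrame, trait: str = "asym_spot",
                   population: str = "population",
                   temperature: str = "temperature_C",
                   table: pd.DataFrame | None = None,
                   measurement_trait: str | None = None,
                   ) -> tuple[list[AsymmetryGroupSummary], AnovaTable]:
    """Per-cell DA tests plus the fixed-effects ANOVA of signed asymmetry.

    ``trait`` names a signed-asymmetry column (right minus left) of the
    individual table. When the replicate-level measurement table (and the
    matching raw trait name) is supplied, each cell's DA test is the side
    term of the mixed ANOVA; otherwise a one-sample t test of A against 0.
    The returned ANOVA decomposes A over temperature + population +
    temperature x population.
    """
    df = individuals.dropna(subset=[trait])
    summaries = []
    for (pop, t), g in df.groupby([population, temperature], observed=True):
        a = g[trait].to_numpy(float)
        if len(a) < 2:
            summaries.append(AsymmetryGroupSummary(pop, t, len(a),
                             float(np.mean(a)) if len(a) else np.nan, np.nan,
                             np.nan, np.nan, "skipped", ["n < 2"]))
            continue
        if table is not None and measurement_trait is not None:
            res = sides_mixed_anova(table, measurement_trait,
                                    group={population: pop, temperature: t})
            summaries.append(AsymmetryGroupSummary(
                pop, t, res.n_individuals, res.da_estimate,
                float(np.std(a, ddof=1)), res.F_DA, res.p_DA,
                "mixed-anova", res.flags))
        else:
            tt = stats.ttest_1samp(a, 0.0)
            summaries.append(AsymmetryGroupSummary(
                pop, t, len(a), float(np.mean(a)), float(np.std(a, ddof=1)),
                float(tt.statistic), float(tt.pvalue), "one-sample-t"))
    spec = ModelSpec(trait, [temperature, population,
                             f"{temperature}:{population}"],
                     factors=(temperature, population))
    anova = fit_linear_model(df, spec)
    return summaries, anova


def levene_fa_test(groups: list, center: str = "mean"):
    """Levene's test for equal FA spread across groups of signed asymmetries.

    Centering at the group mean removes each group's DA before comparing
    spreads (switchable to median). Returns (F, (df1, df2), p, per-group sd).
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 3 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 3 each")
    sds = [float(np.std(a, ddof=1)) for a in arrays]
    if any(s == 0 for s in sds):
        return np.nan, (len(arrays) - 1, sum(map(len, arrays)) - len(arrays)), \
            np.nan, sds
    res = stats.levene(*arrays, center=center)
    df1 = len(arrays) - 1
    df2 = sum(map(len, arrays)) - len(arrays)
    return float(res.statistic), (df1, df2), float(res.pvalue), sds


def da_slope_comparison(individuals: pd.DataFrame, trait: str = "asym_ratio",
                        population: str = "population",
                        temperature: str = "temperature_C"):
    """Temperature-vs-asymmetry slope per population, compared pairwise.

    Returns (per-population RegressionFit dict, {(popA, popB): (t, df, p)}).
    """
    df = individuals.dropna(subset=[trait])
    fits = {}
    xy = {}
    for pop, g in df.groupby(population, observed=True):
        if g[temperature].nunique() < 2:
            raise ValueError(f"population {pop!r} has < 2 temperature levels")
        x = g[temperature].to_numpy(float)
        y = g[trait].to_numpy(float)
        fits[pop] = simple_regression(x, y)
        xy[pop] = (x, y)
    pops = sorted(xy)
    pairwise = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            pairwise[(a, b)] = pairwise_slope_ttest(xy[a], xy[b])
    return fits, pairwise
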