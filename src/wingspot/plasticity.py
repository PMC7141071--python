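"""Fixed-effects linear models for reaction-norm (plasticity) analyses.

The workhorse is an ordinary-least-squares ANOVA engine with sequential
(Type-I) sums of squares in declared term order — the decomposition behind
``phenotype ~ temperature + population + temperature x population``, whose
interaction term is the test for plasticity differences among populations —
plus simple temperature regressions, the spot-on-wing ANCOVA with a
covariate x factor term for slope heterogeneity, pairwise slope t tests,
and Cohen's d.

Factors are treatment-coded against the first level in sorted order; the
coding never affects sums of squares or F tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class RankDeficiencyError(np.linalg.LinAlgError):
    """A model term is aliased with earlier terms (e.g. empty design cells)."""


@dataclass
class ModelSpec:
    """Response and ordered term list of one fixed-effects model.

    Terms are column names, optionally joined by ``:`` for a pairwise
    interaction; interactions may only involve terms already declared as
    main effects. Numeric columns enter as continuous covariates unless
    named in ``factors``; non-numeric columns are always factors.
    """

    response: str
    terms: list[str]
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a model needs at least one term")
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t:
                parts = t.split(":")
                if len(parts) != 2 or any(p not in mains for p in parts):
                    raise ValueError(
                        f"interaction {t!r} must pair two declared main effects")


@dataclass
class AnovaTable:
    """Per-term SS/df/MS/F/p with the residual line and model r-squared."""

    table: pd.DataFrame          # indexed by term, plus a "Residual" row
    n: int
    r_squared: float

    def F(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    @property
    def df_residual(self) -> int:
        return int(self.table.loc["Residual", "df"])


@dataclass
class RegressionFit:
    intercept: float
    slope: float
    slope_se: float
    r_squared: float
    F: float
    p: float
    n: int


def _encode(df: pd.DataFrame, name: str, factors: tuple[str, ...]) -> tuple[np.ndarray, int]:
    col = df[name]
    if name in factors or not pd.api.types.is_numeric_dtype(col):
        levels = np.asarray(sorted(pd.unique(col)))
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
        X = np.column_stack([(col.to_numpy() == lev).astype(float)
                             for lev in levels[1:]])
        return X, len(levels) - 1
    return col.to_numpy(float).reshape(-1, 1), 1


def _term_matrix(df, term, factors):
    if ":" in term:
        a, b = term.split(":")
        Xa, _ = _encode(df, a, factors)
        Xb, _ = _encode(df, b, factors)
        cols = [Xa[:, i] * Xb[:, j]
                for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
        return np.column_stack(cols), Xa.shape[1] * Xb.shape[1]
    return _encode(df, term, factors)


def fit_linear_model(data: pd.DataFrame, spec: ModelSpec) -> AnovaTable:
    """OLS ANOVA with sequential (Type-I) SS in the declared term order.

    Each term's SS is the increase in explained sum of squares when its
    columns are added after all preceding terms; F tests use the residual
    mean square. Rows with missing values in any model column are dropped.

    Raises
    ------
    RankDeficiencyError
        If a term adds fewer independent directions than its degrees of
        freedom (aliased term, e.g. an interaction over empty cells).
    """
    cols = {spec.response}
    for t in spec.terms:
        cols.update(t.split(":"))
    df = data.dropna(subset=sorted(cols))
    n = len(df)
    y = df[spec.response].to_numpy(float)
    total_df = sum(_term_matrix(df, t, spec.factors)[1] for t in spec.terms)
    if n <= total_df + 1:
        raise ValueError(f"n = {n} too small for {total_df} model df")

    ybar = y.mean()
    ss_total = float(((y - ybar) ** 2).sum())
    Q = np.ones((n, 1)) / np.sqrt(n)

    rows = []
    ss_model = 0.0
    for term in spec.terms:
        X, df_term = _term_matrix(df, term, spec.factors)
        scale = float(np.abs(X).max()) or 1.0
        R = X - Q @ (Q.T @ X)
        R = R - Q @ (Q.T @ R)             # re-orthogonalize for stability
        U, s, _ = np.linalg.svd(R, full_matrices=False)
        keep = s > 1e-9 * scale * np.sqrt(n)
        rank = int(keep.sum())
        if rank < df_term:
            raise RankDeficiencyError(
                f"term {term!r} is aliased with earlier terms "
                f"(rank {rank} < df {df_term})")
        Uk = U[:, keep]
        proj = Uk.T @ y
        ss = float(proj @ proj)
        Q = np.hstack([Q, Uk])
        ss_model += ss
        rows.append([term, ss, df_term])

    ss_res = max(ss_total - ss_model, 0.0)
    df_res = n - 1 - total_df
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    out = []
    for term, ss, d in rows:
        ms = ss / d
        if ms_res > 0:
            F = ms / ms_res
            p = float(stats.f.sf(F, d, df_res))
        else:
            F, p = np.inf if ss > 0 else np.nan, 0.0 if ss > 0 else np.nan
        out.append((term, ss, d, ms, F, p))
    out.append(("Residual", ss_res, df_res,
                ss_res / df_res if df_res else np.nan, np.nan, np.nan))
    table = pd.DataFrame(out, columns=["term", "ss", "df", "ms", "F", "p"]
                         ).set_index("term")
    r2 = ss_model / ss_total if ss_total > 0 else np.nan
    return AnovaTable(table=table, n=n, r_squared=float(r2))


def simple_regression(x, y) -> RegressionFit:
    """OLS of y on a single covariate, with slope SE, r-squared, F and p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.var(x) == 0:
        raise ValueError("constant covariate")
    fit = stats.linregress(x, y)
    n = len(x)
    t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
    return RegressionFit(intercept=float(fit.intercept), slope=float(fit.slope),
                         slope_se=float(fit.stderr), r_squared=float(fit.rvalue ** 2),
                         F=float(t ** 2), p=float(fit.pvalue), n=n)


def temperature_regression(individuals: pd.DataFrame, trait: str,
                           temperature: str = "temperature_C") -> RegressionFit:
    """Reaction-norm regression of a trait on temperature as continuous."""
    return simple_regression(individuals[temperature], individuals[trait])


def ancova_slope_heterogeneity(
    individuals: pd.DataFrame,
    response: str = "spot_area",
    covariate: str = "wing_area",
    factor: str = "temperature_C",
) -> tuple[AnovaTable, dict[object, RegressionFit]]:
    """Spot-on-wing ANCOVA with a covariate x temperature interaction.

    The interaction tests whether the spot-wing slope depends on
    temperature; within-level fits report each temperature's own slope and
    r-squared. Levels with fewer than 3 complete cases are excluded with a
    warning.
    """
    df = individuals.dropna(subset=[response, covariate, factor])
    sizes = df.groupby(factor, observed=True).size()
    small = sizes[sizes < 3].index.tolist()
    if small:
        warnings.warn(f"excluding {factor} levels with < 3 points: {small}")
        df = df[~df[factor].isin(small)]
    levels = sorted(pd.unique(df[factor]))
    if len(levels) < 2:
        raise ValueError("need >= 2 usable levels of the grouping factor")
    spec = ModelSpec(response, [covariate, factor, f"{covariate}:{factor}"],
                     factors=(factor,))
    table = fit_linear_model(df, spec)
    per_level = {lev: simple_regression(g[covariate], g[response])
                 for lev, g in df.groupby(factor, observed=True)}
    return table, per_level


def pairwise_slope_ttest(group_a, group_b) -> tuple[float, int, float]:
    """t test for equality of two regression slopes.

    ``t = (b_A - b_B) / sqrt(SE_A^2 + SE_B^2)`` on ``n_A + n_B - 4`` df,
    two-sided. Each group is an (x, y) pair of sequences.
    """
    fa = simple_regression(*group_a)
    fb = simple_regression(*group_b)
    se = np.hypot(fa.slope_se, fb.slope_se)
    df = fa.n + fb.n - 4
    if se == 0:
        t = 0.0 if fa.slope == fb.slope else np.inf
    else:
        t = (fa.slope - fb.slope) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), int(df), p


def cohens_d(x, y) -> float:
    """Standardized mean difference with the (n-1)-weighted pooled sd."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))
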