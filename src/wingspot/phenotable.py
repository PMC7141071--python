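"""Analysis-ready phenotype tables from replicate-level measurements.

A measurement table holds one row per (individual, side, replicate) with
wing and spot areas. This module quantifies digitization repeatability,
collapses replicates and sides to one row per individual (to avoid
pseudoreplication), and derives the relative spot size both as the
spot/wing ratio and as pooled-regression residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RepeatabilityResult:
    """One-way ANOVA of a trait with wing (individual x side) as the factor."""

    trait: str
    n_wings: int
    replicates_per_wing: float
    ss_among: float
    ss_error: float
    df_among: int
    df_error: int
    ms_among: float
    ms_error: float
    F: float
    p: float
    repeatability: float
    degenerate: bool = False


def replicate_error_anova(table: pd.DataFrame, trait: str,
                          group: dict | None = None) -> RepeatabilityResult:
    """Measurement-error ANOVA: among-wing vs replicate residual variance.

    Repeatability is the intraclass correlation
    ``(MS_among - MS_error) / (MS_among + (r - 1) MS_error)`` with r the
    mean replicate count per wing.
    """
    df = _subset(table, group)
    wings = df.groupby(["individual_id", "side"])[trait]
    sizes = wings.size()
    if (sizes >= 2).sum() < 2:
        raise ValueError("no replication: need >= 2 replicates for >= 2 wings")

    grand = df[trait].mean()
    means = wings.mean()
    ss_among = float((sizes * (means - grand) ** 2).sum())
    ss_error = float(((df[trait] - wings.transform("mean")) ** 2).sum())
    df_among = len(sizes) - 1
    df_error = int(sizes.sum()) - len(sizes)
    ms_among = ss_among / df_among
    ms_error = ss_error / df_error if df_error else np.nan
    degenerate = not np.isfinite(ms_error) or (ms_among + ms_error) == 0
    if degenerate:
        F, p, rep = np.nan, np.nan, np.nan
    elif ms_error == 0:
        F, p, rep = np.inf, 0.0, 1.0
    else:
        F = ms_among / ms_error
        p = float(stats.f.sf(F, df_among, df_error))
        r = float(sizes.mean())
        rep = (ms_among - ms_error) / (ms_among + (r - 1) * ms_error)
    return RepeatabilityResult(trait, len(sizes), float(sizes.mean()),
                               ss_among, ss_error, df_among, df_error,
                               ms_among, ms_error, float(F), float(p),
                               float(rep), degenerate)


def _subset(table: pd.DataFrame, group: dict | None) -> pd.DataFrame:
    if not group:
        return table
    m = np.ones(len(table), dtype=bool)
    for k, v in group.items():
        m &= (table[k] == v).to_numpy()
    return table[m]


#: columns of the individual-level table
INDIVIDUAL_COLUMNS = [
    "individual_id", "population", "temperature_C", "complete",
    "wing_area", "spot_area", "ratio",
    "asym_wing", "asym_spot", "asym_ratio",
]


def collapse_to_individuals(table: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: replicate means per side, then side means.

    The ratio is computed from the side-and-replicate-averaged spot and wing
    areas (not as a mean of per-wing ratios). Signed asymmetries are right
    minus left of the side-specific replicate means; they are present only
    for complete individuals (both wings measured), while single-sided
    individuals keep their size traits and are flagged ``complete = False``.
    """
    side_means = (table
                  .groupby(["individual_id", "population", "temperature_C", "side"],
                           observed=True)[["wing_area", "spot_area"]]
                  .mean()
                  .reset_index())
    rows = []
    for (iid, pop, temp), g in side_means.groupby(
            ["individual_id", "population", "temperature_C"], observed=True, sort=True):
        by_side = g.set_index("side")
        complete = {"L", "R"} <= set(by_side.index)
        w = float(by_side["wing_area"].mean())
        s = float(by_side["spot_area"].mean())
        if complete:
            wl, wr = float(by_side.loc["L", "wing_area"]), float(by_side.loc["R", "wing_area"])
            sl, sr = float(by_side.loc["L", "spot_area"]), float(by_side.loc["R", "spot_area"])
            aw, asp = wr - wl, sr - sl
            ar = sr / wr - sl / wl
        else:
            aw = asp = ar = np.nan
        rows.append((iid, pop, temp, complete, w, s, s / w if w else np.nan,
                     aw, asp, ar))
    return pd.DataFrame(rows, columns=INDIVIDUAL_COLUMNS)


def residual_spot_size(individuals: pd.DataFrame) -> pd.Series:
    """Residuals of the pooled OLS fit spot_area ~ wing_area.

    The field's standard guard against allometry artifacts of the raw ratio;
    on an origin-through spot-wing relation the two carry the same signal.
    """
    if len(individuals) < 3:
        raise ValueError("need >= 3 individuals for a residual fit")
    w = individuals["wing_area"].to_numpy(float)
    s = individuals["spot_area"].to_numpy(float)
    if np.var(w) == 0:
        raise ValueError("zero wing-size variance: residual fit undefined")
    slope, intercept = np.polyfit(w, s, 1)
    return pd.Series(s - (intercept + slope * w),
                     index=individuals.index, name="residual_spot")
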