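"""End-to-end orchestration: simulate, measure, tabulate, analyze, report.

A single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])`` (stage indices:
0 images, 1 phenotypes), so stages are independently reproducible. Every
output file carries the configuration hash and seed in a header comment or
JSON field; the summary JSON contains no timestamps and is byte-identical
across reruns of the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymmetry, phenotable, plasticity, segment, synthgen, variability
from . import io as wio

log = logging.getLogger("wingspot")

#: signed-asymmetry column -> replicate-level trait used for the mixed ANOVA
ASYM_TRAITS = {"asym_wing": "wing_area", "asym_spot": "spot_area",
               "asym_ratio": "ratio"}


@dataclass
class PipelineConfig:
    out_dir: str = "wingspot-out"
    seed: int = 0
    n_images: int = 6
    run_images: bool = True
    phenotype_csv: str | None = None     # skip simulation, analyze this table
    image_config: synthgen.ImageSimConfig = field(
        default_factory=synthgen.ImageSimConfig)
    pheno_config: synthgen.PhenoSimConfig = field(
        default_factory=synthgen.PhenoSimConfig)
    seg_params: segment.SegmentationParams = field(
        default_factory=segment.SegmentationParams)
    write_images: bool = False


def stage_seed(global_seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return int(np.random.SeedSequence([global_seed, stage]).generate_state(1)[0]
               % (2 ** 31))


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific configuration (paths excluded)."""
    d = dataclasses.asdict(config)
    for key in ("out_dir", "phenotype_csv", "write_images"):
        d.pop(key, None)
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd) if np.isfinite(x) else (None if np.isnan(x) else x)
    return x


def anova_to_dict(tab: plasticity.AnovaTable) -> dict:
    d = {}
    for term, row in tab.table.iterrows():
        d[str(term)] = {k: _round(float(row[k])) for k in ("ss", "df", "ms", "F", "p")}
    d["n"] = tab.n
    d["r_squared"] = _round(tab.r_squared)
    return d


def run_images_stage(cfg: PipelineConfig, out: Path) -> dict:
    """Simulate n wing photographs, measure them, report recovery errors."""
    base = dataclasses.replace(cfg.image_config)
    seed0 = stage_seed(cfg.seed, 0)
    rows = []
    rel_wing, rel_spot = [], []
    for i in range(cfg.n_images):
        c = dataclasses.replace(base, seed=seed0 + i)
        img, lm, gt = synthgen.simulate_wing_image(c)
        res = segment.measure_image(img, lm, cfg.seg_params)
        rel_wing.append(abs(res.wing_area_px - gt.wing_area_px) / gt.wing_area_px)
        if gt.spot_area_px > 0:
            rel_spot.append(abs(res.spot_area_px - gt.spot_area_px) / gt.spot_area_px)
        rows.append(dict(image=img.source, wing_area_px=res.wing_area_px,
                         wing_area_poly=res.wing_area_poly,
                         spot_area_px=res.spot_area_px,
                         spot_area_poly=res.spot_area_poly,
                         wing_threshold=res.wing_threshold,
                         spot_threshold=res.spot_threshold,
                         gt_wing=gt.wing_area_px, gt_spot=gt.spot_area_px,
                         flags=";".join(res.flags)))
        if cfg.write_images:
            wio.write_image(out / f"{img.source}.png", img)
            wio.write_landmarks(out / f"{img.source}.landmarks.csv", lm)
    wio.write_table(out / "image_measurements.csv", pd.DataFrame(rows),
                    header={"config_hash": config_hash(cfg), "seed": cfg.seed})
    return dict(n=cfg.n_images,
                median_rel_err_wing=_round(float(np.median(rel_wing))),
                median_rel_err_spot=_round(float(np.median(rel_spot))) if rel_spot else None)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write CSVs, a JSON summary, and a text report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    header = {"config_hash": chash, "seed": cfg.seed}
    summary: dict = {"seed": cfg.seed, "config_hash": chash}

    if cfg.run_images:
        log.info("stage: simulate + measure images")
        summary["image_qc"] = run_images_stage(cfg, out)

    log.info("stage: phenotype table")
    if cfg.phenotype_csv:
        table = wio.read_measurement_table(cfg.phenotype_csv)
        summary["phenotypes"] = {"source": str(cfg.phenotype_csv)}
    else:
        pcfg = dataclasses.replace(cfg.pheno_config, seed=stage_seed(cfg.seed, 1))
        table, gt = synthgen.simulate_phenotype_dataset(pcfg)
        if gt.n_resampled:
            log.info("resampled %d nonpositive draws", gt.n_resampled)
        wio.write_table(out / "measurements.csv", table, header=header)
        wio.write_json(out / "measurements.ground_truth.json",
                       {**synthgen.ground_truth_to_dict(gt), **header})
        summary["phenotypes"] = {"source": "simulated",
                                 "n_individuals": gt.n_individuals}
    table = table.copy()
    table["ratio"] = table["spot_area"] / table["wing_area"]

    log.info("stage: tabulate")
    rep = {}
    for trait in ("wing_area", "spot_area"):
        r = phenotable.replicate_error_anova(table, trait)
        rep[trait] = dict(ms_among=_round(r.ms_among), ms_error=_round(r.ms_error),
                          F=_round(r.F), p=_round(r.p),
                          repeatability=_round(r.repeatability))
    summary["repeatability"] = rep
    ind = phenotable.collapse_to_individuals(table)
    ind["residual_spot"] = phenotable.residual_spot_size(ind)
    wio.write_table(out / "individuals.csv", ind, header=header)

    log.info("stage: plasticity")
    plas = {}
    for trait in ("wing_area", "spot_area", "ratio"):
        spec = plasticity.ModelSpec(
            trait, ["temperature_C", "population", "temperature_C:population"],
            factors=("temperature_C", "population"))
        plas[trait] = anova_to_dict(plasticity.fit_linear_model(ind, spec))
    summary["plasticity_anova"] = plas
    regs = {}
    for trait in ("wing_area", "spot_area", "ratio"):
        f = plasticity.temperature_regression(ind, trait)
        regs[trait] = dict(slope=_round(f.slope), r_squared=_round(f.r_squared),
                           F=_round(f.F), p=_round(f.p), n=f.n)
    summary["temperature_regressions"] = regs

    anc, per_level = plasticity.ancova_slope_heterogeneity(ind)
    summary["ancova"] = anova_to_dict(anc)
    summary["spot_wing_slopes"] = {
        str(t): dict(slope=_round(f.slope), r_squared=_round(f.r_squared), n=f.n)
        for t, f in per_level.items()}
    temps = sorted(ind["temperature_C"].unique())
    pw = {}
    for i, ta in enumerate(temps):
        for tb in temps[i + 1:]:
            ga = ind[ind.temperature_C == ta]
            gb = ind[ind.temperature_C == tb]
            t, dfree, p = plasticity.pairwise_slope_ttest(
                (ga.wing_area, ga.spot_area), (gb.wing_area, gb.spot_area))
            pw[f"{ta:g}v{tb:g}"] = dict(t=_round(t), df=dfree, p=_round(p))
    summary["pairwise_slope_tests"] = pw

    pops = sorted(ind["population"].unique())
    cd = {}
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            cd[f"{pa}-{pb}"] = _round(plasticity.cohens_d(
                ind.loc[ind.population == pa, "ratio"],
                ind.loc[ind.population == pb, "ratio"]))
    summary["cohens_d_ratio"] = cd

    log.info("stage: variability")
    cells, tests = variability.cv_table(ind)
    wio.write_table(out / "cv_table.csv", cells, header=header)
    wio.write_table(out / "cv_tests.csv", tests, header=header)
    summary["cv"] = {
        f"{r.trait}|{r.population}|{r.temperature:g}": _round(float(r.cv))
        for r in cells.itertuples()}
    summary["cv_tests_significant"] = int((tests["p"] < 0.05).sum())

    log.info("stage: asymmetry")
    asym: dict = {}
    for acol, mtrait in ASYM_TRAITS.items():
        res = asymmetry.sides_mixed_anova(table, mtrait)
        summaries, aov = asymmetry.da_group_tests(ind, acol)
        groups = {f"{s.population}|{s.temperature:g}":
                  dict(n=s.n, da=_round(s.da_mean), fa_sd=_round(s.fa_sd),
                       p=_round(s.p)) for s in summaries}
        asym[acol] = dict(
            mixed=dict(F_DA=_round(res.F_DA), p_DA=_round(res.p_DA),
                       F_FA=_round(res.F_FA), p_FA=_round(res.p_FA),
                       da_estimate=_round(res.da_estimate),
                       sigma2_fa=_round(res.sigma2_fa),
                       me_fa_ratio=_round(res.me_fa_ratio)),
            anova=anova_to_dict(aov), groups=groups)
        by_temp = [g[acol].dropna().to_numpy()
                   for _, g in ind.groupby("temperature_C")]
        F, dfree, p, sds = asymmetry.levene_fa_test(by_temp)
        asym[acol]["levene_by_temperature"] = dict(
            F=_round(F), df=list(dfree), p=_round(p),
            sds=[_round(s) for s in sds])
    fits, pairwise = asymmetry.da_slope_comparison(ind, "asym_ratio")
    asym["ratio_da_slopes"] = {
        str(p): dict(slope=_round(f.slope, 8), p=_round(f.p)) for p, f in fits.items()}
    asym["ratio_da_slope_tests"] = {
        f"{a}-{b}": dict(t=_round(t), df=d, p=_round(p))
        for (a, b), (t, d, p) in pairwise.items()}
    summary["asymmetry"] = asym

    wio.write_json(out / "summary.json", summary)
    (out / "report.txt").write_text(render_report(summary), encoding="utf-8")
    return summary


def _fmt_f(block: dict, term: str, dfres) -> str:
    t = block[term]
    return f"F_{{{t['df']:g}, {dfres:g}}} = {t['F']:.3f}, p = {t['p']:.3g}"


def render_report(summary: dict) -> str:
    """Human-readable report in the field's F_{df1, df2} = x, p = y style."""
    lines = [f"wingspot pipeline report (seed {summary['seed']}, "
             f"config {summary['config_hash']})", ""]
    if "image_qc" in summary:
        q = summary["image_qc"]
        lines += ["Image measurement QC:",
                  f"  n = {q['n']}, median relative error: "
                  f"wing {q['median_rel_err_wing']:.4f}, "
                  f"spot {q['median_rel_err_spot']:.4f}", ""]
    lines.append("Plasticity two-way ANOVAs (temperature + population + interaction):")
    for trait, block in summary["plasticity_anova"].items():
        dfres = block["Residual"]["df"]
        lines.append(f"  {trait}: temperature "
                     + _fmt_f(block, "temperature_C", dfres)
                     + "; interaction "
                     + _fmt_f(block, "temperature_C:population", dfres)
                     + f"; r2 = {block['r_squared']:.2f}")
    lines.append("")
    lines.append("Spot-on-wing ANCOVA (slope heterogeneity):")
    anc = summary["ancova"]
    lines.append("  wing x temperature "
                 + _fmt_f(anc, "wing_area:temperature_C", anc["Residual"]["df"]))
    for t, s in summary["spot_wing_slopes"].items():
        lines.append(f"  slope at {t} C: {s['slope']:.4f} (r2 = {s['r_squared']:.2f})")
    lines.append("")
    lines.append("Coefficients of variation (trait | population | temperature):")
    for key, cv in summary["cv"].items():
        lines.append(f"  {key}: {cv:.3f}")
    lines.append("")
    lines.append("Asymmetry:")
    for acol in ASYM_TRAITS:
        m = summary["asymmetry"][acol]["mixed"]
        lines.append(f"  {acol}: DA = {m['da_estimate']:.4g} "
                     f"(F = {m['F_DA']:.3f}, p = {m['p_DA']:.3g}); "
                     f"FA F = {m['F_FA']:.3f}, p = {m['p_FA']:.3g}; "
                     f"interaction/error MS ratio = {m['me_fa_ratio']:.1f}")
    return "\n".join(lines) + "\n"
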