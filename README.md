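# wingspot

Morphometrics of a pigmented wing spot relative to wing size in flies
reared across developmental temperatures — for evolutionary biologists
studying phenotypic plasticity, canalization and developmental
instability of a putatively sexually selected trait.

The package covers the full chain from pixels to inference:

- **`wingspot.synthgen`** — synthetic wing photographs (pale wing, sharp
  outline, dark spot with a fuzzy blurred boundary) with exact pixel-count
  ground truth, and replicate-level phenotype tables drawn from an explicit
  generative model of the rearing design (3 populations × 3 temperatures,
  two wings per individual, two replicate measurements per wing).
- **`wingspot.segment`** — area measurement: landmark-chord proximal crop,
  Otsu/half-max thresholding, largest-component contours, areas both as
  filled-pixel counts and by the shoelace (Green's theorem) formula
  |½ Σᵢ (xᵢyᵢ₊₁ − xᵢ₊₁yᵢ)|.
- **`wingspot.phenotable`** — repeatability ANOVA, collapsing replicates
  and sides to individuals, ratio ρ = S/W and pooled-OLS residual spot
  size, signed asymmetries A = R − L.
- **`wingspot.plasticity`** — sequential-SS (Type-I) fixed-effects ANOVA
  engine (`phenotype ~ temperature + population + temperature × population`,
  the interaction being the plasticity-difference test), temperature
  regressions, spot-on-wing ANCOVA with a wing × temperature term,
  pairwise slope t tests, Cohen's d.
- **`wingspot.variability`** — coefficients of variation per
  population × temperature cell and the modified signed-likelihood-ratio
  (MSLR) test of CV equality across k normal samples (statistic ~ χ²ₖ₋₁).
- **`wingspot.asymmetry`** — the two-way mixed ANOVA (individuals random,
  side fixed, replicates in the error term) separating directional
  asymmetry (side, tested over the side × individual MS), fluctuating
  asymmetry (side × individual, tested over replicate error,
  σ̂²_FA = (MS_int − MS_err)/r) and measurement error, plus Levene tests
  and DA-slope comparisons.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Run the end-to-end demo (simulate images → measure → tabulate → analyze):

```sh
wingspot demo --seed 1 --out demo-out
```

`demo-out/report.txt` then contains (excerpt):

```
Image measurement QC:
  n = 6, median relative error: wing 0.0034, spot 0.0094

Plasticity two-way ANOVAs (temperature + population + interaction):
  wing_area: temperature F_{2, 382} = 3040.309, p = 0; interaction F_{4, 382} = 13.471, p = 0; r2 = 0.94
  spot_area: temperature F_{2, 382} = 344.205, p = 0; interaction F_{4, 382} = 1.854, p = 0.118; r2 = 0.65
  ratio: temperature F_{2, 382} = 1.770, p = 0.172; interaction F_{4, 382} = 0.575, p = 0.681; r2 = 0.03

Asymmetry:
  asym_spot: DA = 0.4345 (F = 140.592, p = 0); FA F = 22.073, p = 0; interaction/error MS ratio = 22.1
```

Reading this: the measured wing areas land within ~0.3 % of the simulated
ground truth (spot ~1 %). Wing size responds strongly to temperature
(F₂,₃₈₂ = 3040, r² = 0.94) with a detectable population difference in
plasticity (the interaction, F₄,₃₈₂ = 13.5) — both put into the generator —
while the spot/wing ratio is nearly temperature-stable (r² = 0.03). The
spot shows right-biased directional asymmetry (DA = +0.43 against a
simulated offset of 0.4) and fluctuating asymmetry far exceeding
measurement error (interaction/error mean-square ratio ≈ 22). The same
run writes `summary.json` (machine-readable, byte-identical across reruns
of the same seed), the CV table with MSLR flags, and all per-stage CSVs.

The library surface mirrors the CLI:

```python
import wingspot as ws

table, truth = ws.simulate_phenotype_dataset(ws.PhenoSimConfig(seed=1))
ind = ws.collapse_to_individuals(table)
anova = ws.fit_linear_model(
    ind, ws.ModelSpec("ratio",
                      ["temperature_C", "population", "temperature_C:population"],
                      factors=("temperature_C", "population")))
print(anova.table)
```

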