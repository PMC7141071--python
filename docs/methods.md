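# Methods

`wingspot` studies the size of a dark wing spot relative to wing size in
flies reared at different developmental temperatures, and the variability
and bilateral asymmetry of both traits. Everything downstream of the raw
photographs is implemented here: a synthetic-data generator with exact
ground truth, contour-based area measurement, and the statistical program
(plasticity ANOVAs, CV-equality testing, asymmetry decomposition). This
note records the models, the defaults and why, the numerical choices, and
what the synthetic data do and do not show about real data.

## Image model and measurement

A synthetic wing photograph is a pale membrane (default gray 180) on a
lighter background (230) carrying a dark distal spot (60). The wing
silhouette is a smooth convex blob — an ellipse whose distal half is
broadened and proximal half narrowed by a taper factor — rasterized by
evaluating the boundary inequality at pixel centers. Only areas, never
shapes, enter the analyses, so no venation is drawn. The spot is a disk
whose binary mask is Gaussian-blurred (default sigma 3 px) before
compositing: the wing/background edge is sharp while the spot boundary is
fuzzy, which is the measurement problem the real assay faces. Ground-truth
areas are the **pre-blur mask pixel counts**, an estimator-independent
definition; for a symmetric blur the half-max contour of the blurred edge
coincides with the pre-blur outline, so the default spot threshold (below)
is unbiased up to discretization. A spot whose disk plus a 3-sigma blur
apron would cross the wing outline is rejected as a configuration error
rather than silently clipped.

Measurement mirrors the real procedure:

1. **Proximal crop.** The infinite line through two user-supplied landmarks
   is the discard chord; every pixel on the proximal side (the side with
   the smaller share of darker-than-threshold pixels) is set to the
   background level. The generator places its landmarks 2 % of the wing
   length from the proximal margin, so the crop removes well under 1 % of
   the wing.
2. **Wing outline.** Otsu's threshold computed on the pixels above the
   darkest decile — excluding the spot's dark tail so the split always
   lands on the wing/background edge, not the spot/membrane edge — then the
   largest connected dark component (floor: 1 % of the raster). Outer
   contour only: interior brighter patches count as wing.
3. **Spot.** Within the wing mask, threshold at the midpoint between the
   membrane's modal gray and the darkest 1 % quantile (a half-max rule),
   largest component, floor 0.1 % of the raster. If the modal-to-dark
   contrast is under 10 gray levels the wing is reported spotless. A manual
   threshold can replace either automatic rule; in the real assay the
   manual contrast choice is the dominant source of measurement error, and
   the knob exists precisely to emulate it (the algorithm itself is
   deterministic).
4. **Areas.** Each structure is reported as the filled-pixel count
   (primary) and the shoelace polygon area of the 0.5-level contour
   (cross-check); the two agree to within O(perimeter) pixels. With a
   physical scale set, areas are also given in square micrometres.

On 50 default synthetic images the median absolute area error is about
0.3 % for the wing and about 1 % for the spot. Left/right is metadata
supplied per image, never inferred from pixels, because slide mounting can
flip chirality.

## Phenotype generative model

For individual *i* of population *p* at temperature *t* (areas in
arbitrary units, roughly thousands of pixels):

    W_i = a_p + b_p t + e_i,     e_i ~ N(0, (cv_W (a_p + b_p t))^2)
    S_i = c_t + m_t W_i + u_i,   u_i ~ N(0, sigma_t^2)

Side values are the latent trait ± delta/2 (right positive — directional
asymmetry, DA) plus independent N(0, sigma_FA^2) per side (fluctuating
asymmetry, FA); each replicate measurement adds independent
N(0, sigma_ME^2) (measurement error, ME). The output is a long-format
table, one row per (individual, side, replicate).

Defaults encode the phenomena of the emulated design — three populations ×
{16, 22, 28} °C, two wings per individual, two replicate measurements per
wing, individuals assigned to isofemale-line labels (8–17 per line, split
round-robin across temperatures; lines are bookkeeping only and are never
modeled):

| parameter | default | rationale |
|---|---|---|
| wing intercepts a_p | 250–270 | wing ≈ 90–170 units across temperatures |
| wing slopes b_p | −5.2 … −6.2 per °C | wing size falls steeply with temperature, slightly differently per population |
| cv_W | 0.05 | among-individual wing CV flat in temperature (~0.04–0.07) |
| spot slopes m_t | 0.12 / 0.08 / 0.01 | spot–wing coupling weakens with heat |
| spot residual sd sigma_t | 3.0 / 2.5 / 6.0 | spot and ratio variability inflate at 28 °C |
| delta_spot | 0.4 (delta_wing 0) | right-biased spot DA, no wing DA |
| sigma_FA (wing, spot) | 1.5, 0.5 | FA clearly above ME |
| sigma_ME (wing, spot) | 0.5, 0.15 | replicate error far below FA |

These magnitudes are free parameters of the simulation, documented here as
choices; they are not estimates for any real population. Nonpositive
simulated areas are redrawn (up to 100 times, then an error) rather than
truncated, to avoid silently distorting the distributions; a config flag
switches to fail-fast.

**What the generator does not emulate:** real wings have venation, uneven
illumination, mounting artifacts and damaged margins; real measurement
error is a human contrast choice, not Gaussian; line structure carries
variance the generator assigns to individuals; traits are generated
normal, whereas real areas are bounded and right-skewed. Passing tests
therefore demonstrate that the estimators recover the truth of *this*
model, not that the assay is unbiased on real photographs.

## Statistical program

**Tabulation.** Replicate measurements are averaged per wing, then sides
per individual. The relative spot size is the ratio of the averaged spot
and wing areas (not the mean of per-wing ratios); signed asymmetries are
right minus left of the side-specific replicate means, defined only for
complete (two-winged) individuals, which are the unit of all asymmetry
analyses. Digitization repeatability is a one-way ANOVA with wing as the
factor; the intraclass correlation is
(MS_among − MS_err) / (MS_among + (r − 1) MS_err).

**Linear models.** The engine fits ordinary least squares with
treatment-coded factors and reports **sequential (Type-I) sums of
squares** in the declared term order — always (temperature, population,
interaction) or (wing size, temperature, interaction) — matching the
classical decomposition this style of analysis reports; on balanced
designs the sequential SS equal the textbook cell-mean formulas exactly.
Terms are orthogonalized incrementally (SVD per block, tolerance 1e-9
relative); a term spanning fewer independent directions than its degrees
of freedom (empty cells, collinearity) raises a rank-deficiency error
naming the term. Temperature is categorical in the experimental ANOVAs
(2 df) and continuous in the regression fits. p-values are unadjusted
throughout; rows with missing values are dropped per model, so residual
df vary with trait completeness. Effect sizes are Cohen's d with the
(n−1)-weighted pooled sd, and r² from the fits.

**Slope heterogeneity.** The spot-on-wing ANCOVA adds a wing × temperature
interaction; per-temperature slopes and r² are reported alongside. Two
slopes are compared by t = (b_A − b_B)/sqrt(SE_A² + SE_B²) on
n_A + n_B − 4 df.

**CV equality (MSLR).** Among-individual variability is the coefficient of
variation; equality across k groups is tested with the modified
signed-likelihood-ratio test for normal samples: the profile likelihood
ratio for a common CV tau, computed with n_i replaced by n_i − 1 and
unbiased variances (the small-sample modification), referred to
chi-square(k − 1). For fixed tau the group-mean MLE has a closed form;
the profile is maximized by bounded 1-D optimization (log-likelihood
tolerance ~1e-10) with a bracket of tau_0 × [1/100, 100] around the
weighted mean CV. A group with zero variance among nonzero ones yields an
infinite statistic flagged `boundary`; all-zero variances return p = 1
with a `degenerate` flag. Monte Carlo: type-I error 0.035–0.065 at
n = 20/group, and the null statistic tracks chi-square(2) (KS < 0.05 at
n = 200/group). The Table-style CV matrix compares, within each
population × trait, the largest-CV temperature against the other two
(unadjusted, flagged at alpha .05 and .1).

**Asymmetry.** The two-way mixed ANOVA (individuals random, side fixed,
with replicated measurements) partitions each trait into individual, side
(DA), side × individual (FA) and replicate error (ME). F_DA tests the
side MS over the interaction MS — the standard mixed-model denominator,
which the source analyses leave implicit — and F_FA tests the interaction
over the error MS; E[MS_err] = sigma_ME² and
E[MS_int] = sigma_ME² + r sigma_FA², so sigma_FA² is estimated by moments
and floored at zero with a flag. The DA estimate equals the grand mean of
per-individual (R − L) replicate means in balanced designs. Balanced
designs use the exact cell-means decomposition; unbalanced replicate
counts fall back to sequential SS and are flagged. With one replicate per
wing FA is not separable from ME and the function refuses. Ratio
asymmetry enters through side-specific replicate-level ratios.
Group-level analyses on signed asymmetries: one-sample t (or the mixed
ANOVA where replicates are available) per cell, a fixed-effects ANOVA of
A over temperature × population, Levene's test centered at the **group
mean** (removing DA before comparing FA spread; switchable to median),
and pairwise comparisons of temperature-vs-asymmetry slopes among
populations. FA magnitude is reported both as the sd of signed A and as
the moment estimate; the MS_int/MS_err ratio is reported per group as the
FA-versus-ME dominance check.

## Ratio versus residual

The raw ratio S/W can mislead under allometry, so residuals from the
pooled OLS fit of spot on wing are provided as the alternative relative
size. The two are equivalent — same ranks, same significance pattern —
precisely when the spot–wing relation passes through the origin with a
near-common slope and the pooled slope is identified from within-cell
variation. Outside that regime they genuinely diverge: when mean wing
size tracks temperature strongly, the pooled regression absorbs
temperature contrasts that the ratio retains; the concordance test
simulates the equivalence regime (slopes 0.16/0.15/0.14, c_t = 0, wing
trend −0.3 per °C, within-cell wing CV 3 %) and observes ≥ 95 % pattern
agreement, while the divergence outside it is expected behavior, not a
defect.

## Pipeline and reproducibility

One global seed is fanned out to stages via
`SeedSequence([seed, stage_index])`. Every CSV carries the configuration
hash and seed as `#`-comment headers; the summary JSON contains no
timestamps and is byte-identical across reruns (paths are excluded from
the hash). Problem sizes in the shipped checks — 50 images, 200–1000
Monte-Carlo replicates per calibration, 36–200 individuals per simulated
cell — are chosen so every rate has a Monte-Carlo standard error of about
one percentage point or less while the whole suite stays quick on a
laptop.

## Known limitations

- The segmentation assumes a single wing per image, darker than its
  background, with the spot the darkest structure; color images and
  illumination gradients are out of scope.
- The MSLR test assumes normal samples with positive means; area traits
  satisfy this comfortably, heavily skewed traits would not.
- Mixed-ANOVA p-values assume normal errors; no antisymmetry diagnostics
  (bimodality of R − L) are provided.
- Isofemale-line and vial variance components are deliberately not
  modeled or estimated.
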