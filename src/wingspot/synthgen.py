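"""Synthetic wing images and phenotype datasets with known ground truth.

The image generator renders the measurement target of the real assay: a pale
wing membrane on a lighter background with a sharp outline, carrying a dark
distal spot whose boundary is fuzzy (Gaussian-blurred). The phenotype
generator realizes the experimental design of the rearing study — three
geographic populations crossed with three developmental temperatures, two
wings per individual, replicated measurements per wing — from an explicit
generative model whose parameters (reaction-norm slopes, spot–wing coupling,
directional and fluctuating asymmetry, measurement error) are the exact
quantities the downstream statistics estimate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclass
class WingImage:
    """A single-channel raster with optional physical scale.

    Parameters
    ----------
    pixels : ndarray
        2-D uint8 (or uint16) array, origin top-left, y downward.
    scale_um_per_px : float, optional
        Physical edge length of one pixel in micrometres.
    source : str
        Identifier of the image (file stem or simulation tag).
    """

    pixels: np.ndarray
    scale_um_per_px: float | None = None
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("WingImage requires a nonempty 2-D single-channel raster")
        self.pixels = px


@dataclass(frozen=True)
class LandmarkPair:
    """Two points (x, y) in pixel coordinates marking the proximal crop chord."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("landmarks must be distinct points")


@dataclass
class ImageSimConfig:
    """Geometry, photometry and noise of one synthetic wing image.

    The wing outline is a smooth convex closed curve (a tapered ellipse):
    only areas, never shapes, enter the analyses, so no venation is drawn.
    Gray levels satisfy spot < wing < background (the spot is darkest).
    """

    width: int = 560
    height: int = 360
    wing_semi_major: float = 220.0   # px, distal axis along +x
    wing_semi_minor: float = 105.0   # px
    tip_taper: float = 0.25          # 0 = ellipse; >0 narrows the proximal end
    spot_offset_frac: float = 0.18   # spot center behind the wing tip, fraction of wing length
    spot_radius: float = 32.0        # px; 0 = spotless wing
    spot_blur_sigma: float = 3.0     # px, fuzziness of the spot boundary
    background_gray: int = 230
    wing_gray: int = 180
    spot_gray: int = 60
    noise_sigma: float = 3.0
    landmark_frac: float = 0.02      # chord position from the proximal margin, fraction of wing length
    scale_um_per_px: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.spot_gray < self.wing_gray < self.background_gray <= 255):
            raise ConfigError("gray levels must satisfy 0 <= spot < wing < background <= 255")
        if self.spot_blur_sigma < 0 or self.noise_sigma < 0:
            raise ConfigError("blur and noise sigmas must be >= 0")
        if self.spot_radius < 0:
            raise ConfigError("spot radius must be >= 0")
        if not (0.0 < self.landmark_frac < 0.5):
            raise ConfigError("landmark_frac must lie in (0, 0.5)")
        if min(self.width, self.height) < 8:
            raise ConfigError("image too small")


@dataclass
class ImageGroundTruth:
    """Pre-blur mask pixel counts — the estimator-independent area truth."""

    wing_area_px: float
    spot_area_px: float
    ratio: float
    wing_area_distal_px: float      # wing pixels distal to the landmark chord
    wing_area_units: float | None = None
    spot_area_units: float | None = None


def _wing_mask(cfg: ImageSimConfig) -> np.ndarray:
    """Pixel-center rasterization of the tapered-ellipse wing silhouette.

    The outline is |y - cy| <= b sqrt(1 - u^2) (1 + taper * u) with
    u = (x - cx) / a: an ellipse whose distal half (+x) is broadened and
    proximal half narrowed — a smooth convex wing-like blob. Evaluating the
    inequality at pixel centers makes the ground-truth mask analytic and
    estimator-independent.
    """
    cx, cy = cfg.width / 2.0, cfg.height / 2.0
    yy, xx = np.mgrid[0:cfg.height, 0:cfg.width]
    u = (xx - cx) / cfg.wing_semi_major
    half = cfg.wing_semi_minor * np.sqrt(np.clip(1.0 - u ** 2, 0.0, None)) \
        * (1.0 + cfg.tip_taper * u)
    return (np.abs(u) <= 1.0) & (np.abs(yy - cy) <= half)


def simulate_wing_image(
    config: ImageSimConfig,
) -> tuple[WingImage, LandmarkPair, ImageGroundTruth]:
    """Render one synthetic wing photograph with exact area ground truth.

    Returns the 8-bit image, the two proximal-margin landmarks defining the
    crop chord, and the ground truth (pre-blur filled-mask pixel counts for
    wing and spot, their ratio, and the wing pixels distal to the chord).

    Raises
    ------
    ConfigError
        If the spot (including its blur apron) would cross the wing outline.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    wing_mask = _wing_mask(config)
    if not wing_mask.any():
        raise ConfigError("wing outline rasterized to an empty mask")

    cx = w / 2.0
    cy = h / 2.0
    wing_len = 2.0 * config.wing_semi_major

    spot_mask = np.zeros((h, w), dtype=bool)
    if config.spot_radius > 0:
        sx = cx + config.wing_semi_major - config.spot_offset_frac * wing_len
        sy = cy
        # the spot and its blur apron must stay inside the wing
        dist_inside = ndi.distance_transform_edt(wing_mask)
        margin = config.spot_radius + 3.0 * config.spot_blur_sigma
        if dist_inside[int(round(sy)), int(round(sx))] <= margin:
            raise ConfigError(
                "spot (radius %.1f px, blur %.1f px) would cross the wing outline"
                % (config.spot_radius, config.spot_blur_sigma)
            )
        yy, xx = np.mgrid[0:h, 0:w]
        spot_mask = (xx - sx) ** 2 + (yy - sy) ** 2 <= config.spot_radius ** 2

    # landmark chord: vertical line near the proximal margin
    x0 = cx - config.wing_semi_major + config.landmark_frac * wing_len
    col = int(round(x0))
    rows = np.nonzero(wing_mask[:, col])[0]
    if rows.size == 0:
        raise ConfigError("landmark chord misses the wing mask")
    landmarks = LandmarkPair((float(col), float(rows[0])), (float(col), float(rows[-1])))

    cols = np.arange(w)[None, :]
    wing_area = float(wing_mask.sum())
    spot_area = float(spot_mask.sum())
    distal_area = float((wing_mask & (cols >= col)).sum())

    img = np.full((h, w), float(config.background_gray))
    img[wing_mask] = float(config.wing_gray)
    if spot_mask.any():
        b = spot_mask.astype(float)
        if config.spot_blur_sigma > 0:
            b = gaussian(b, sigma=config.spot_blur_sigma, preserve_range=True)
        img = img * (1.0 - b) + float(config.spot_gray) * b
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = ImageGroundTruth(
        wing_area_px=wing_area,
        spot_area_px=spot_area,
        ratio=spot_area / wing_area if wing_area else 0.0,
        wing_area_distal_px=distal_area,
    )
    if config.scale_um_per_px is not None:
        s2 = config.scale_um_per_px ** 2
        gt.wing_area_units = wing_area * s2
        gt.spot_area_units = spot_area * s2

    image = WingImage(img, scale_um_per_px=config.scale_um_per_px,
                      source=f"sim-seed{config.seed}")
    return image, landmarks, gt


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

#: canonical column order of the replicate-level measurement table
MEASUREMENT_COLUMNS = [
    "population", "temperature_C", "line", "individual_id",
    "side", "replicate", "wing_area", "spot_area",
]


@dataclass
class PhenoSimConfig:
    """Generative model of the rearing experiment.

    Latent model, for individual i of population p at temperature t (areas in
    thousands of pixels):

        W_i = a_p + b_p * t + e_i,        e_i ~ N(0, (wing_cv * (a_p + b_p t))^2)
        S_i = c_t + m_t * W_i + u_i,      u_i ~ N(0, spot_resid_sd[t]^2)

    Wing spread scales with the cell mean (a fixed among-individual CV), so
    the wing coefficient of variation stays roughly flat across
    temperatures while the spot and ratio CVs inflate at 28 C through the
    temperature-dependent residual sd.

    Side values are W_i ± delta_wing/2 and S_i ± delta_spot/2 (right = +)
    plus independent N(0, sigma_fa^2) per side; every replicate measurement
    adds independent N(0, sigma_me^2). Defaults encode the phenomena the
    study design exhibits: wing size falls with temperature, the spot–wing
    coupling weakens and its residual spread grows at 28 °C, and the spot
    shows a right-biased directional asymmetry.
    """

    populations: tuple[str, ...] = ("Dayton", "Paris", "Sapporo")
    temperatures: tuple[float, ...] = (16.0, 22.0, 28.0)
    lines_per_population: int = 10
    individuals_per_line: tuple[int, int] = (8, 17)
    replicates: int = 2
    # wing reaction norms per population (intercept, slope per deg C)
    wing_intercept: dict[str, float] = field(
        default_factory=lambda: {"Dayton": 265.0, "Paris": 270.0, "Sapporo": 255.0})
    wing_slope: dict[str, float] = field(
        default_factory=lambda: {"Dayton": -6.2, "Paris": -6.0, "Sapporo": -5.2})
    wing_cv: float = 0.05
    # spot-on-wing regression per temperature
    spot_intercept: dict[float, float] = field(
        default_factory=lambda: {16.0: 14.0, 22.0: 17.0, 28.0: 19.0})
    spot_slope: dict[float, float] = field(
        default_factory=lambda: {16.0: 0.12, 22.0: 0.08, 28.0: 0.01})
    spot_resid_sd: dict[float, float] = field(
        default_factory=lambda: {16.0: 3.0, 22.0: 2.5, 28.0: 6.0})
    # asymmetry components (right minus left offsets; per-side FA; per-replicate ME)
    delta_wing: float = 0.0
    delta_spot: float = 0.4
    sigma_fa_wing: float = 1.5
    sigma_fa_spot: float = 0.5
    sigma_me_wing: float = 0.5
    sigma_me_spot: float = 0.15
    on_nonpositive: str = "resample"   # or "fail"
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 2:
            raise ConfigError("replicates per wing must be >= 2 "
                              "(required to separate FA from measurement error)")
        if list(self.temperatures) != sorted(set(self.temperatures)):
            raise ConfigError("temperatures must be strictly increasing")
        lo, hi = self.individuals_per_line
        if not (1 <= lo <= hi):
            raise ConfigError("individuals_per_line must be a valid integer range")
        for name in ("wing_cv", "sigma_fa_wing", "sigma_fa_spot",
                     "sigma_me_wing", "sigma_me_spot"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.spot_resid_sd.values()):
            raise ConfigError("spot_resid_sd values must be >= 0")
        if self.on_nonpositive not in ("resample", "fail"):
            raise ConfigError("on_nonpositive must be 'resample' or 'fail'")
        for p in self.populations:
            if p not in self.wing_intercept or p not in self.wing_slope:
                raise ConfigError(f"missing wing reaction norm for population {p!r}")
        for t in self.temperatures:
            if t not in self.spot_slope or t not in self.spot_intercept \
                    or t not in self.spot_resid_sd:
                raise ConfigError(f"missing spot model for temperature {t!r}")


@dataclass
class PhenoGroundTruth:
    """The generative parameters a correct analysis should recover."""

    delta_wing: float
    delta_spot: float
    sigma_fa_wing: float
    sigma_fa_spot: float
    sigma_me_wing: float
    sigma_me_spot: float
    spot_slope_per_temperature: dict[float, float]
    wing_slope_per_population: dict[str, float]
    n_individuals: int = 0
    n_resampled: int = 0


def simulate_phenotype_dataset(
    config: PhenoSimConfig,
) -> tuple[pd.DataFrame, PhenoGroundTruth]:
    """Draw a long-format replicate-level measurement table.

    One row per (individual, side, replicate). Nonpositive simulated areas
    are redrawn up to 100 times per individual (default) or raise, per
    ``config.on_nonpositive``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    n_ind = 0
    n_resampled = 0

    for p in config.populations:
        a_p, b_p = config.wing_intercept[p], config.wing_slope[p]
        for t in config.temperatures:
            if a_p + b_p * t <= 0:
                raise ConfigError(f"nonpositive mean wing size for {p} at {t} C")
        # a line's yield is split round-robin across the temperature levels
        for li in range(config.lines_per_population):
            line = f"{p}-L{li + 1:02d}"
            yield_n = int(rng.integers(config.individuals_per_line[0],
                                       config.individuals_per_line[1] + 1))
            for j in range(yield_n):
                t = config.temperatures[j % len(config.temperatures)]
                m_t = config.spot_slope[t]
                c_t = config.spot_intercept[t]
                s_t = config.spot_resid_sd[t]
                w_mu = a_p + b_p * t
                for attempt in range(101):
                    w_lat = w_mu + rng.normal(0.0, config.wing_cv * w_mu)
                    s_lat = c_t + m_t * w_lat + rng.normal(0.0, s_t)
                    vals = {}
                    ok = True
                    for side, sgn in (("L", -1.0), ("R", 1.0)):
                        w_side = (w_lat + sgn * config.delta_wing / 2.0
                                  + rng.normal(0.0, config.sigma_fa_wing))
                        s_side = (s_lat + sgn * config.delta_spot / 2.0
                                  + rng.normal(0.0, config.sigma_fa_spot))
                        reps = []
                        for r in range(1, config.replicates + 1):
                            wm = w_side + rng.normal(0.0, config.sigma_me_wing)
                            sm = s_side + rng.normal(0.0, config.sigma_me_spot)
                            if wm <= 0 or sm <= 0:
                                ok = False
                            reps.append((r, wm, sm))
                        vals[side] = reps
                    if ok:
                        break
                    if config.on_nonpositive == "fail":
                        raise ConfigError("nonpositive simulated area "
                                          f"(population {p}, T={t})")
                    n_resampled += 1
                else:
                    raise ConfigError("could not draw positive areas after "
                                      "100 resampling attempts")
                n_ind += 1
                iid = f"{p}-T{t:g}-{n_ind:05d}"
                for side in ("L", "R"):
                    for r, wm, sm in vals[side]:
                        rows.append((p, t, line, iid, side, r, wm, sm))

    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    gt = PhenoGroundTruth(
        delta_wing=config.delta_wing,
        delta_spot=config.delta_spot,
        sigma_fa_wing=config.sigma_fa_wing,
        sigma_fa_spot=config.sigma_fa_spot,
        sigma_me_wing=config.sigma_me_wing,
        sigma_me_spot=config.sigma_me_spot,
        spot_slope_per_temperature=dict(config.spot_slope),
        wing_slope_per_population=dict(config.wing_slope),
        n_individuals=n_ind,
        n_resampled=n_resampled,
    )
    return table, gt


def ground_truth_to_dict(gt) -> dict:
    """JSON-serializable view of either ground-truth dataclass."""
    d = dataclasses.asdict(gt)
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = {str(kk): vv for kk, vv in v.items()}
        else:
            out[k] = v
    return out
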