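"""Wing and spot area measurement from grayscale photographs.

Mirrors the assay's measurement chain: a chord through two proximal
landmarks discards the (often damaged) wing base, the wing outline is
extracted as the largest dark connected component under an automatic
contrast threshold, the spot as the largest extra-dark component inside the
wing, and each area is reported twice — as the filled-pixel count and as
the shoelace (Green's theorem) polygon area of the extracted contour.

Coordinates are pixel coordinates, origin top-left, x rightward, y downward.
Contours are (N, 2) float arrays of (x, y) vertices, implicitly closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

from .synthgen import LandmarkPair, WingImage


class SegmentationError(RuntimeError):
    pass


@dataclass
class SegmentationParams:
    """Thresholding and component-size knobs.

    ``manual_threshold`` overrides the automatic (Otsu) wing threshold,
    emulating the manual contrast adjustment that is the dominant source of
    measurement error in the real assay; ``spot_threshold`` likewise
    overrides the half-max spot rule (midpoint of the wing-membrane modal
    gray and the darkest ``dark_quantile`` of in-wing grays).
    """

    manual_threshold: float | None = None
    spot_threshold: float | None = None
    min_wing_frac: float = 0.01       # of the raster, floor for "a wing was found"
    min_spot_frac: float = 0.001      # of the raster, floor for "a spot was found"
    dark_quantile: float = 0.01
    min_spot_contrast: float = 10.0   # gray levels; below this the wing is spotless
    boundary_contact_frac: float = 0.25   # spot/wing contact flagged beyond this


@dataclass
class SegmentationResult:
    wing_contour: np.ndarray
    spot_contour: np.ndarray | None
    wing_area_px: float
    wing_area_poly: float
    spot_area_px: float
    spot_area_poly: float
    wing_threshold: float
    spot_threshold: float | None
    chord: LandmarkPair | None
    flags: list[str] = field(default_factory=list)
    wing_area_units: float | None = None
    spot_area_units: float | None = None

    @property
    def ratio(self) -> float:
        return self.spot_area_px / self.wing_area_px if self.wing_area_px else 0.0


def polygon_area(contour: np.ndarray) -> float:
    """Area of a closed simple polygon by the shoelace (Green's theorem) sum.

    ``|0.5 * sum(x_i * y_{i+1} - x_{i+1} * y_i)|``; orientation-independent.
    Self-intersecting input is the caller's responsibility.
    """
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
        raise ValueError("polygon_area requires >= 3 vertices of shape (N, 2)")
    x, y = c[:, 0], c[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


def _auto_wing_threshold(img: np.ndarray) -> float:
    """Otsu threshold for the wing/background edge.

    Computed on the pixels above the darkest decile so that a large dark
    spot cannot capture the split: the wing/background contrast, not the
    spot/membrane contrast, defines the wing outline.
    """
    vals = img.ravel()
    sel = vals[vals >= np.quantile(vals, 0.10)]
    if np.ptp(sel) == 0:
        raise SegmentationError("no contrast: cannot find a wing threshold")
    return float(threshold_otsu(sel))


def _background_fill(img: np.ndarray, thr: float) -> float:
    bright = img[img > thr]
    return float(np.median(bright)) if bright.size else float(img.max())


def crop_proximal(image: WingImage, landmarks: LandmarkPair) -> WingImage:
    """Blank every pixel on the proximal side of the landmark chord.

    The distal side — kept untouched — is the side of the infinite line
    through the two landmarks holding the larger share of darker-than-
    threshold (foreground) pixels. If either side holds no foreground the
    crop is skipped with a warning and ``meta['crop_noop'] = True``.
    """
    img = image.pixels
    (x1, y1), (x2, y2) = landmarks.p1, landmarks.p2
    if (x1, y1) == (x2, y2):
        raise ValueError("degenerate chord: coincident landmarks")
    h, w = img.shape
    for x, y in (landmarks.p1, landmarks.p2):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError("landmark outside the raster")

    try:
        thr = _auto_wing_threshold(img)
    except SegmentationError:
        warnings.warn("crop chord: no image contrast; no-op")
        out = WingImage(img.copy(), scale_um_per_px=image.scale_um_per_px,
                        source=image.source, meta=dict(image.meta))
        out.meta["crop_noop"] = True
        return out
    fg = img <= thr
    yy, xx = np.mgrid[0:h, 0:w]
    s = (x2 - x1) * (yy - y1) - (y2 - y1) * (xx - x1)
    n_pos = int(np.count_nonzero(fg & (s > 0)))
    n_neg = int(np.count_nonzero(fg & (s < 0)))
    out = WingImage(img.copy(), scale_um_per_px=image.scale_um_per_px,
                    source=image.source, meta=dict(image.meta))
    if n_pos == 0 or n_neg == 0:
        if n_pos == 0 and n_neg == 0:
            warnings.warn("crop chord: no foreground on either side; no-op")
        out.meta["crop_noop"] = True
        return out
    distal_sign = 1.0 if n_pos >= n_neg else -1.0
    proximal = (s * distal_sign) < 0
    out.pixels[proximal] = _background_fill(img, thr)
    out.meta["crop_noop"] = False
    return out


def _mask_contour(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of a binary mask, as (x, y) vertices."""
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("component produced no contour")
    c = max(contours, key=len)
    return c[:, ::-1].copy()   # (row, col) -> (x, y)


def _largest_component(mask: np.ndarray, min_pixels: float):
    lab, n = ndi.label(mask)
    if n == 0:
        return None
    sizes = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_pixels:
        return None
    return lab == best


def _segment_wing_full(image: WingImage, params: SegmentationParams):
    img = image.pixels
    thr = params.manual_threshold
    if thr is None:
        thr = _auto_wing_threshold(img)
    fg = img <= thr
    if fg.all():
        raise SegmentationError("no wing found (no background brighter than threshold)")
    mask = _largest_component(fg, params.min_wing_frac * img.size)
    if mask is None:
        raise SegmentationError("no wing found (no dark component above the size floor)")
    return _mask_contour(mask), mask, thr


def segment_wing(image: WingImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Closed outer contour of the largest darker-than-background component."""
    contour, _, _ = _segment_wing_full(image, params or SegmentationParams())
    return contour


def _wing_mask_from_contour(contour: np.ndarray, shape) -> np.ndarray:
    rr, cc = draw_polygon(contour[:, 1], contour[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _segment_spot_full(image: WingImage, wing_contour: np.ndarray,
                       params: SegmentationParams, wing_mask=None):
    img = image.pixels
    if wing_mask is None:
        wing_mask = _wing_mask_from_contour(wing_contour, img.shape)
    vals = img[wing_mask]
    thr = params.spot_threshold
    if thr is None:
        # half-max rule: midpoint of membrane modal gray and the darkest tail
        counts = np.bincount(vals.astype(np.int64), minlength=256)
        mode = float(np.argmax(counts))
        dark = float(np.quantile(vals, params.dark_quantile))
        if mode - dark < params.min_spot_contrast:
            return None, None, None, []     # no dark tail: spotless wing
        thr = (mode + dark) / 2.0
    mask = _largest_component((img <= thr) & wing_mask,
                              params.min_spot_frac * img.size)
    if mask is None:
        return None, None, float(thr), []
    flags: list[str] = []
    # contact with the wing boundary, as a fraction of the spot's own edge
    edge = mask & ~ndi.binary_erosion(mask)
    outside = ~ndi.binary_erosion(wing_mask)
    contact = np.count_nonzero(edge & outside) / max(np.count_nonzero(edge), 1)
    if contact > params.boundary_contact_frac:
        flags.append("boundary-truncated")
    return _mask_contour(mask), mask, float(thr), flags


def segment_spot(image: WingImage, wing_contour: np.ndarray,
                 params: SegmentationParams | None = None) -> np.ndarray | None:
    """Spot contour inside the wing, or None for spotless wings."""
    contour, _, _, _ = _segment_spot_full(image, wing_contour,
                                          params or SegmentationParams())
    return contour


def measure_image(image: WingImage, landmarks: LandmarkPair | None,
                  params: SegmentationParams | None = None) -> SegmentationResult:
    """Full measurement of one photograph: crop, segment, both area estimators.

    Deterministic given (image, landmarks, params): the real assay's
    measurement error enters only through the manual threshold choice.
    """
    params = params or SegmentationParams()
    flags: list[str] = []
    if landmarks is not None:
        try:
            image = crop_proximal(image, landmarks)
        except ValueError as e:
            raise SegmentationError(f"crop: {e}") from e
        if getattr(image, "meta", {}).get("crop_noop"):
            flags.append("crop-noop")
    try:
        wing_contour, wing_mask, wing_thr = _segment_wing_full(image, params)
    except SegmentationError as e:
        raise SegmentationError(f"wing: {e}") from e
    try:
        spot_contour, spot_mask, spot_thr, spot_flags = _segment_spot_full(
            image, wing_contour, params, wing_mask=wing_mask)
    except SegmentationError as e:
        raise SegmentationError(f"spot: {e}") from e
    flags += spot_flags
    if spot_contour is None:
        flags.append("spot-absent")

    res = SegmentationResult(
        wing_contour=wing_contour,
        spot_contour=spot_contour,
        wing_area_px=float(np.count_nonzero(wing_mask)),
        wing_area_poly=polygon_area(wing_contour),
        spot_area_px=float(np.count_nonzero(spot_mask)) if spot_mask is not None else 0.0,
        spot_area_poly=polygon_area(spot_contour) if spot_contour is not None else 0.0,
        wing_threshold=float(wing_thr),
        spot_threshold=spot_thr,
        chord=landmarks,
        flags=flags,
    )
    if image.scale_um_per_px is not None:
        s2 = image.scale_um_per_px ** 2
        res.wing_area_units = res.wing_area_px * s2
        res.spot_area_units = res.spot_area_px * s2
    return res
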