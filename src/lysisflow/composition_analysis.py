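"""Clot-section composition: synthetic histology, ROI sampling, COV.

Clot analogs sectioned and H&E-stained show red blood cells (dark red),
fibrin (pink) and white blood cells (blue).  Composition is quantified
by sampling five 2 mm x 2 mm regions of interest (ROIs) at random,
measuring the RBC pixel percentage in each, and summarising homogeneity
as the coefficient of variation COV = SD / mean across ROIs.  Lower COV
means a more evenly mixed clot.

The synthetic generator draws per-pixel classes from a spatially
correlated RBC-probability field: a Gaussian random field g (unit
variance, ~1 mm correlation length) perturbs the mean RBC fraction on
the logit scale,

    p(x) = sigmoid(logit(p0) + h * g(x)),

so ``heterogeneity`` h is the SD of the local log-odds.  h = 0 gives a
homogeneous clot; the named presets encode field strengths whose 5-ROI
COV lands near the values observed for well-mixed (~0.18) and poorly
mixed (~0.49) clots.  Non-RBC pixels split between fibrin, WBC and
background in fixed proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidGeometryError, UndefinedCOVError

__all__ = [
    "CLASS_RBC",
    "CLASS_FIBRIN",
    "CLASS_WBC",
    "CLASS_BACKGROUND",
    "CLASS_PALETTE",
    "LabelImage",
    "ROISpec",
    "CompositionResult",
    "HETEROGENEITY_PRESETS",
    "generate_histology",
    "sample_rois",
    "rbc_fraction_and_cov",
    "cov_from_summary",
    "render_color",
    "classify_rendered",
    "stretch_pct",
]

CLASS_RBC = 0
CLASS_FIBRIN = 1
CLASS_WBC = 2
CLASS_BACKGROUND = 3

#: Rendering palette (RGB): RBC dark red, fibrin pink, WBC blue, background off-white.
CLASS_PALETTE = np.array(
    [
        [139, 0, 0],
        [255, 182, 193],
        [60, 60, 200],
        [245, 245, 240],
    ],
    dtype=np.uint8,
)

#: Logit-scale field SDs calibrated so that 5 random 2-mm ROIs give the
#: COV levels seen for well-mixed and control clots (~0.18 and ~0.49).
HETEROGENEITY_PRESETS: dict[str, float] = {
    "well_mixed": 0.62,
    "control": 2.30,
}

#: Relative shares of fibrin / WBC / background among non-RBC pixels.
_NON_RBC_SHARES = np.array([0.80, 0.05, 0.15])


@dataclass(frozen=True)
class LabelImage:
    """Per-pixel ground-truth class map plus physical pixel size."""

    classes: np.ndarray  # 2-D int array of CLASS_* values
    pixel_size: float  # um per pixel

    def __post_init__(self) -> None:
        arr = np.asarray(self.classes)
        if arr.ndim != 2:
            raise InvalidGeometryError("classes must be a 2-D array")
        if self.pixel_size <= 0:
            raise InvalidGeometryError("pixel_size must be positive")
        object.__setattr__(self, "classes", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned ROI: 0-based top-left origin, half-open pixel extents."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise InvalidGeometryError("ROI extents must be positive")
        if self.row < 0 or self.col < 0:
            raise InvalidGeometryError("ROI origin must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(
            self.col, self.col + self.width
        )

    def overlaps(self, other: "ROISpec") -> bool:
        return not (
            self.row + self.height <= other.row
            or other.row + other.height <= self.row
            or self.col + self.width <= other.col
            or other.col + other.width <= self.col
        )


@dataclass(frozen=True)
class CompositionResult:
    """Per-ROI RBC percentages with their mean, SD and COV."""

    rbc_pct: tuple[float, ...]
    mean: float
    sd: float
    cov: float


def generate_histology(
    mean_rbc_pct: float,
    heterogeneity: float | str = 0.0,
    seed: int = 0,
    size: tuple[int, int] = (500, 500),
    pixel_size: float = 20.0,
    correlation_length_um: float = 1000.0,
) -> LabelImage:
    """Synthesise a seeded clot section with known class map.

    ``heterogeneity`` is either the logit-scale field SD or a preset
    name from :data:`HETEROGENEITY_PRESETS`.  Default geometry is a
    10 x 10 mm section at 20 um/pixel.
    """
    if not 0 <= mean_rbc_pct <= 100:
        raise InvalidGeometryError("mean_rbc_pct must be in [0, 100]")
    if isinstance(heterogeneity, str):
        try:
            h = HETEROGENEITY_PRESETS[heterogeneity]
        except KeyError:
            raise InvalidGeometryError(
                f"unknown heterogeneity preset {heterogeneity!r}; "
                f"available: {', '.join(HETEROGENEITY_PRESETS)}"
            ) from None
    else:
        h = float(heterogeneity)
    if h < 0:
        raise InvalidGeometryError("heterogeneity must be >= 0")

    rng = np.random.default_rng(seed)
    p0 = mean_rbc_pct / 100.0
    if h > 0 and 0 < p0 < 1:
        sigma_px = correlation_length_um / pixel_size
        field = rng.standard_normal(size)
        field = ndimage.gaussian_filter(field, sigma=sigma_px, mode="wrap")
        sd = field.std()
        if sd > 0:
            field /= sd
        logit = math.log(p0 / (1.0 - p0)) + h * field
        p = 1.0 / (1.0 + np.exp(-logit))
    else:
        p = np.full(size, p0)

    u = rng.random(size)
    is_rbc = u < p
    # partition the remaining probability mass among non-RBC classes
    residual = (u - p) / np.maximum(1.0 - p, 1e-12)
    cuts = np.cumsum(_NON_RBC_SHARES)
    classes = np.full(size, CLASS_BACKGROUND, dtype=np.uint8)
    classes[residual < cuts[1]] = CLASS_WBC
    classes[residual < cuts[0]] = CLASS_FIBRIN
    classes[is_rbc] = CLASS_RBC
    return LabelImage(classes=classes, pixel_size=pixel_size)


def sample_rois(
    image: LabelImage,
    n: int = 5,
    roi_mm: float = 2.0,
    seed: int = 0,
    max_tries: int = 20000,
) -> list[ROISpec]:
    """Place ``n`` random, pairwise non-overlapping square ROIs.

    ROI side is ``roi_mm`` millimetres at the image's pixel size.
    """
    side = int(round(roi_mm * 1000.0 / image.pixel_size))
    rows, cols = image.shape
    if side <= 0 or side > rows or side > cols:
        raise InvalidGeometryError(
            f"ROI of {roi_mm} mm ({side} px) does not fit a {rows}x{cols} px image"
        )
    rng = np.random.default_rng(seed)
    rois: list[ROISpec] = []
    tries = 0
    while len(rois) < n:
        if tries >= max_tries:
            raise InvalidGeometryError(
                f"could not place {n} non-overlapping {side}-px ROIs "
                f"in a {rows}x{cols} image after {max_tries} tries"
            )
        tries += 1
        cand = ROISpec(
            row=int(rng.integers(0, rows - side + 1)),
            col=int(rng.integers(0, cols - side + 1)),
            height=side,
            width=side,
        )
        if all(not cand.overlaps(r) for r in rois):
            rois.append(cand)
    return rois


def _roi_fraction(classes: np.ndarray, roi: ROISpec) -> float:
    rs, cs = roi.slices()
    if rs.stop > classes.shape[0] or cs.stop > classes.shape[1]:
        raise InvalidGeometryError(f"ROI {roi} extends outside the image")
    patch = classes[rs, cs]
    return float(np.mean(patch == CLASS_RBC))


def rbc_fraction_and_cov(
    image: LabelImage, rois: list[ROISpec]
) -> CompositionResult:
    """Per-ROI RBC percentage and the across-ROI COV = SD/mean.

    SD is the sample (n-1) standard deviation over ROIs.
    """
    if not rois:
        raise InvalidGeometryError("need at least one ROI")
    pcts = np.array([100.0 * _roi_fraction(image.classes, r) for r in rois])
    mean = float(pcts.mean())
    sd = float(pcts.std(ddof=1)) if len(pcts) > 1 else 0.0
    if mean == 0.0:
        if sd > 0:
            raise UndefinedCOVError("COV undefined: mean RBC% is 0 with nonzero SD")
        cov = 0.0
    else:
        cov = sd / mean
    return CompositionResult(rbc_pct=tuple(pcts), mean=mean, sd=sd, cov=cov)


def cov_from_summary(mean: float, sd: float) -> float:
    """COV from a printed mean +/- SD summary (same SD/mean definition)."""
    if mean == 0:
        raise UndefinedCOVError("COV undefined for zero mean")
    if sd < 0:
        raise InvalidGeometryError("sd must be >= 0")
    return sd / mean


def render_color(image: LabelImage) -> np.ndarray:
    """Render the class map with the fixed H&E-like palette (RGB uint8)."""
    return CLASS_PALETTE[image.classes]


def classify_rendered(rgb: np.ndarray) -> np.ndarray:
    """Recover a class map from a rendered image by nearest palette color.

    This is the color-threshold step used when only a rendered section
    (no ground-truth map) is available; on images rendered by
    :func:`render_color` it is exact.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise InvalidGeometryError("expected an H x W x 3 color image")
    diff = rgb[..., None, :].astype(np.int32) - CLASS_PALETTE[None, None, :, :].astype(np.int32)
    dist = np.square(diff).sum(axis=-1)
    return np.argmin(dist, axis=-1).astype(np.uint8)


def stretch_pct(length_initial: float, length_current: float) -> float:
    """Percent elongation of a clot under shear (sign-preserving)."""
    if length_initial <= 0:
        raise InvalidGeometryError(
            f"length_initial must be positive, got {length_initial}"
        )
    return 100.0 * (length_current - length_initial) / length_initial
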