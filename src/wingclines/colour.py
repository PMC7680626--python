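"""Wing colour, pattern and contrast metrics from calibrated photographs.

Reimplements the measurement macro as a deterministic pipeline:
affine grey calibration against patches of known nominal grey,
flood-fill wing segmentation, principal-axis orientation and splitting
of the wing into thirds, luminance grey means, Otsu separation of the
brown ground colour from the cream spot pattern, their areas, and the
cream-minus-brown contrast statistic. Grey values use the full 8-bit
scale, 0 (black) to 255 (white); mean grey is a lightness measure,
the inverse of the degree of melanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, segmentation
from skimage.filters import threshold_otsu

#: ITU-R 601 luminance weights for RGB -> 8-bit grey.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

#: Flood-fill tolerance (grey units) for background identification.
DEFAULT_FLOOD_TOLERANCE = 12.0

#: Minimum separation of Otsu class means, in grey units, below which
#: the wing is treated as patternless.
MIN_CLASS_SEPARATION = 10.0

#: Wear grade at which wings are excluded from colour analyses.
WEAR_SCALE_EXCLUDED = 4


class CalibrationError(ValueError):
    """Raised when grey calibration cannot be fitted."""


class SegmentationError(ValueError):
    """Raised when the wing cannot be separated from the background."""


class PatternError(ValueError):
    """Raised when no separable brown/cream pattern exists."""


@dataclass
class CalibrationPatch:
    """A rectangular reference patch of known nominal grey.

    ``bounds`` is (row0, row1, col0, col1), half-open.
    """

    bounds: tuple[int, int, int, int]
    nominal_grey: float


@dataclass
class WingImage:
    """An 8-bit RGB wing photograph with calibration metadata."""

    pixels: np.ndarray                      # H x W x 3 uint8
    attachment_point: tuple[int, int]       # (row, col) wing-body junction
    patches: list[CalibrationPatch] = field(default_factory=list)
    wing_mask: np.ndarray | None = None
    specimen_id: str = ""
    wing: str = "forewing"
    surface: str = "dorsal"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        h, w = self.pixels.shape[:2]
        r, c = self.attachment_point
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("attachment point outside image")


@dataclass
class WingColourMetrics:
    """Grey-level summaries of one wing surface."""

    specimen_id: str
    wing: str
    surface: str
    mean_grey_whole: float
    mean_grey_basal_third: float
    brown_mean: float
    cream_mean: float
    brown_area_px: int
    cream_area_px: int
    proportion_brown: float
    contrast: float
    excluded: bool = False


def to_grey(pixels: np.ndarray, weights: tuple[float, float, float] = LUMINANCE_WEIGHTS) -> np.ndarray:
    """RGB -> grey by luminance weighting, as float in [0, 255]."""
    return np.asarray(pixels, dtype=float) @ np.asarray(weights, dtype=float)


def measure_patch(image: WingImage, patch: CalibrationPatch) -> float:
    """Mean grey of a calibration patch region."""
    r0, r1, c0, c1 = patch.bounds
    h, w = image.pixels.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise CalibrationError(f"patch region {patch.bounds} outside image")
    return float(to_grey(image.pixels[r0:r1, c0:c1]).mean())


def calibrate_grey(image: WingImage) -> WingImage:
    """Undo an affine lighting distortion using the calibration patches.

    Fits nominal = gain * measured + offset by least squares over all
    patches and applies the map to every channel, clipping to [0, 255].
    Requires at least two patches with distinct nominal greys.
    """
    if len(image.patches) < 2:
        raise CalibrationError("need at least two calibration patches")
    nominals = np.array([p.nominal_grey for p in image.patches], dtype=float)
    if np.ptp(nominals) == 0.0:
        raise CalibrationError("calibration patches have identical nominal greys")
    measured = np.array([measure_patch(image, p) for p in image.patches])
    if np.ptp(measured) == 0.0:
        raise CalibrationError(
            "all patches measure identically; cannot fit gain/offset"
        )
    design = np.column_stack([measured, np.ones_like(measured)])
    (gain, offset), *_ = np.linalg.lstsq(design, nominals, rcond=None)
    corrected = np.clip(
        np.asarray(image.pixels, dtype=float) * gain + offset, 0.0, 255.0
    )
    return WingImage(
        pixels=corrected.round().astype(np.uint8),
        attachment_point=image.attachment_point,
        patches=image.patches,
        wing_mask=image.wing_mask,
        specimen_id=image.specimen_id,
        wing=image.wing,
        surface=image.surface,
    )


def segment_wing(
    image: WingImage, flood_tolerance: float = DEFAULT_FLOOD_TOLERANCE
) -> np.ndarray:
    """Separate the wing from an approximately uniform background.

    The background is the union of flood fills seeded at the four image
    corners; the wing is the largest connected non-background
    component, with interior holes filled. Calibration-patch regions
    are masked out first so they can never be mistaken for wing.
    """
    grey = to_grey(image.pixels)
    h, w = grey.shape
    background = np.zeros((h, w), dtype=bool)
    for seed in ((0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)):
        background |= segmentation.flood(grey, seed, tolerance=flood_tolerance)
    candidate = ~background
    for patch in image.patches:
        r0, r1, c0, c1 = patch.bounds
        candidate[r0:r1, c0:c1] = False
    labels = measure.label(candidate, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no foreground component found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    wing = labels == int(np.argmax(counts))
    wing = ndimage.binary_fill_holes(wing)
    if wing.sum() < 0.01 * h * w:
        raise SegmentationError(
            f"wing component covers {wing.sum()} px "
            f"(< 1% of image); segmentation failed"
        )
    return wing


def orient_and_split_thirds(
    wing_mask: np.ndarray, attachment_point: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition the wing into basal/middle/distal thirds.

    The longest axis is the principal axis of the mask pixel
    coordinates; two cuts perpendicular to it at 1/3 and 2/3 of its
    extent partition the mask exactly. The basal third is the
    partition whose extent contains (or is nearest to) the projection
    of the wing-body attachment point.
    """
    mask = np.asarray(wing_mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if coords.size == 0:
        raise SegmentationError("empty wing mask")
    centre = coords.mean(axis=0)
    centred = coords - centre
    cov = centred.T @ centred / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]

    proj = centred @ axis
    lo, hi = proj.min(), proj.max()
    cut1 = lo + (hi - lo) / 3.0
    cut2 = lo + 2.0 * (hi - lo) / 3.0

    att = np.asarray(attachment_point, dtype=float) - centre
    att_proj = float(att @ axis)
    att_proj = min(max(att_proj, lo), hi)  # nearest-boundary fallback

    bands = np.full(len(coords), 1, dtype=int)   # middle by default
    bands[proj <= cut1] = 0
    bands[proj > cut2] = 2
    att_band = 0 if att_proj <= cut1 else (2 if att_proj > cut2 else 1)
    if att_band == 1:
        # Attachment should sit at an end of the long axis; snap to the
        # nearer extreme band.
        att_band = 0 if (att_proj - lo) <= (hi - att_proj) else 2

    rows = coords[:, 0].astype(int)
    cols = coords[:, 1].astype(int)
    masks = []
    order = [att_band, 1, 2 - att_band]  # basal, middle, distal
    for band in order:
        m = np.zeros_like(mask)
        sel = bands == band
        m[rows[sel], cols[sel]] = True
        masks.append(m)
    return masks[0], masks[1], masks[2]


def mean_grey(
    image: WingImage | np.ndarray,
    mask: np.ndarray,
    weights: tuple[float, float, float] = LUMINANCE_WEIGHTS,
) -> float:
    """Mean luminance grey value over the masked pixels."""
    pixels = image.pixels if isinstance(image, WingImage) else image
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(to_grey(pixels, weights)[mask].mean())


def segment_brown_cream(
    image: WingImage, wing_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split the wing into brown (dark) and cream (light) classes.

    Otsu's threshold on the within-wing grey histogram; the class with
    the lower mean is brown. An effectively unimodal wing (class means
    closer than 10 grey units, or a single grey level) has no
    separable pattern and is rejected.
    """
    grey = to_grey(image.pixels)
    values = grey[np.asarray(wing_mask, dtype=bool)]
    if values.size == 0:
        raise SegmentationError("empty wing mask")
    if np.ptp(values) == 0.0:
        raise PatternError("no separable pattern: uniform grey wing")
    thresh = threshold_otsu(values)
    dark = wing_mask & (grey <= thresh)
    light = wing_mask & (grey > thresh)
    if not dark.any() or not light.any():
        raise PatternError("no separable pattern: threshold degenerate")
    dark_mean = grey[dark].mean()
    light_mean = grey[light].mean()
    if light_mean - dark_mean < MIN_CLASS_SEPARATION:
        raise PatternError(
            f"no separable pattern: class means {dark_mean:.1f} and "
            f"{light_mean:.1f} are closer than {MIN_CLASS_SEPARATION} grey units"
        )
    return dark, light


def colour_metrics(image: WingImage, wear_scale: int) -> WingColourMetrics:
    """Full per-wing colour/pattern measurement.

    Wings with scale damage grade 4 are excluded (returned with the
    ``excluded`` flag and no metrics). Otherwise: segmentation ->
    thirds -> whole/basal grey means -> brown/cream separation ->
    areas, proportion brown, and contrast = cream mean - brown mean.
    Stage failures propagate with the stage named.
    """
    if wear_scale == WEAR_SCALE_EXCLUDED:
        return WingColourMetrics(
            specimen_id=image.specimen_id,
            wing=image.wing,
            surface=image.surface,
            mean_grey_whole=float("nan"),
            mean_grey_basal_third=float("nan"),
            brown_mean=float("nan"),
            cream_mean=float("nan"),
            brown_area_px=0,
            cream_area_px=0,
            proportion_brown=float("nan"),
            contrast=float("nan"),
            excluded=True,
        )
    try:
        wing_mask = image.wing_mask if image.wing_mask is not None else segment_wing(image)
    except SegmentationError as exc:
        raise SegmentationError(f"segment_wing: {exc}") from exc
    try:
        basal, _, _ = orient_and_split_thirds(wing_mask, image.attachment_point)
    except SegmentationError as exc:
        raise SegmentationError(f"orient_and_split_thirds: {exc}") from exc
    whole = mean_grey(image, wing_mask)
    basal_mean = mean_grey(image, basal)
    try:
        brown_mask, cream_mask = segment_brown_cream(image, wing_mask)
    except PatternError as exc:
        raise PatternError(f"segment_brown_cream: {exc}") from exc
    brown_mean = mean_grey(image, brown_mask)
    cream_mean = mean_grey(image, cream_mask)
    brown_area = int(brown_mask.sum())
    cream_area = int(cream_mask.sum())
    return WingColourMetrics(
        specimen_id=image.specimen_id,
        wing=image.wing,
        surface=image.surface,
        mean_grey_whole=whole,
        mean_grey_basal_third=basal_mean,
        brown_mean=brown_mean,
        cream_mean=cream_mean,
        brown_area_px=brown_area,
        cream_area_px=cream_area,
        proportion_brown=brown_area / (brown_area + cream_area),
        contrast=cream_mean - brown_mean,
    )
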