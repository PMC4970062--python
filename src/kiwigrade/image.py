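"""Camera-side measurement pipeline.

Turns a top-view RGB image of a single kiwifruit resting on 1 mm coordinate
paper into calibrated physical measurements: fruit length (the long side of
the axis-aligned minimal bounding rectangle), the maximum equatorial-section
diameter MaDES (the short side), and the projected area PA.

The pipeline is the classical machine-vision chain: NTSC grayscale
conversion, Otsu global thresholding, connected-component area filtering to
drop small noise blobs, bounding-rectangle / pixel-count size extraction, and
conversion from pixels to millimetres through the calibration ratio RA
(pixels per square millimetre of the coordinate paper), where

    L     = PL  / sqrt(RA)      [mm]
    MaDES = PW  / sqrt(RA)      [mm]
    PA    = PPA / RA            [mm^2]

with PL, PW the bounding-rectangle side lengths in pixels and PPA the white
pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from skimage.measure import label as _cc_label

from .errors import (
    CalibrationError,
    DegenerateImageError,
    EmptyForegroundError,
    KiwigradeError,
)

__all__ = [
    "Calibration",
    "PixelMeasurement",
    "FruitMeasurement",
    "PipelineConfig",
    "MeasurementResult",
    "rgb_to_gray",
    "otsu_threshold",
    "binarize",
    "remove_small_regions",
    "min_bounding_rect",
    "calibrate",
    "to_physical",
    "measure_image",
]

# NTSC luma weights (sum to 1).
_NTSC_WEIGHTS = (0.299, 0.587, 0.114)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical calibration: ``ra`` is pixels per mm^2."""

    ra: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ra) or self.ra <= 0:
            raise CalibrationError(f"calibration ratio must be positive, got {self.ra}")

    @property
    def px_per_mm(self) -> float:
        return float(np.sqrt(self.ra))


@dataclass(frozen=True)
class PixelMeasurement:
    """Raw pixel-space sizes: bounding-rectangle long/short side and white count."""

    pl: int
    pw: int
    ppa: int

    def __post_init__(self) -> None:
        if not (self.pl >= self.pw >= 1):
            raise KiwigradeError(f"need pl >= pw >= 1, got pl={self.pl}, pw={self.pw}")
        if not (1 <= self.ppa <= self.pl * self.pw):
            raise KiwigradeError(
                f"white count ppa={self.ppa} outside [1, pl*pw={self.pl * self.pw}]"
            )


@dataclass(frozen=True)
class FruitMeasurement:
    """The four camera/scale-measurable quantities for one fruit.

    ``pa_mm2`` is stored in mm^2; estimation models consume cm^2 through
    :meth:`as_predictors` (1 cm^2 = 100 mm^2).
    """

    weight_g: float
    length_mm: float
    mades_mm: float
    pa_mm2: float

    def __post_init__(self) -> None:
        for name in ("weight_g", "length_mm", "mades_mm", "pa_mm2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise KiwigradeError(f"{name} must be strictly positive, got {v}")
        if self.length_mm < self.mades_mm:
            raise KiwigradeError(
                f"length ({self.length_mm}) must be >= MaDES ({self.mades_mm}) "
                "by the long-side convention"
            )

    @property
    def pa_cm2(self) -> float:
        return self.pa_mm2 / 100.0

    def as_predictors(self) -> dict[str, float]:
        """Predictor mapping in the units the estimation models expect."""
        return {
            "weight_g": self.weight_g,
            "pa_cm2": self.pa_cm2,
            "length_mm": self.length_mm,
            "mades_mm": self.mades_mm,
        }


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for :func:`measure_image`.

    ra
        Calibration ratio override (pixels per mm^2). When ``None`` the grid
        is detected from the top border strip of the image itself.
    invert
        Set when the fruit is darker than the background after thresholding.
    hair_offset_mm
        Systematic size offset subtracted from length and MaDES to compensate
        for the fruit-hair fringe included in the silhouette. Default 0
        (no correction applied).
    connectivity
        Pixel connectivity for component labeling: 2 = 8-connectivity
        (default, robust to hairy boundaries), 1 = 4-connectivity.
    min_area_fraction
        Components strictly smaller than this fraction of the largest one
        are removed.
    """

    ra: float | None = None
    grid_pitch_mm: float = 1.0
    invert: bool = False
    hair_offset_mm: float = 0.0
    connectivity: int = 2
    min_area_fraction: float = 1.0 / 20.0
    calibration_border_frac: float = 0.12


@dataclass(frozen=True)
class MeasurementResult:
    """Full record of one image measurement, including pipeline diagnostics."""

    fruit: FruitMeasurement
    pixels: PixelMeasurement
    calibration: Calibration
    threshold: int
    n_components_removed: int


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _as_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DegenerateImageError(f"expected HxWx3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DegenerateImageError("empty image")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise KiwigradeError("RGB channel values must lie in [0, 255]")
    return arr


def _as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise DegenerateImageError(f"expected HxW gray array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DegenerateImageError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise KiwigradeError("gray values must lie in [0, 255]")
    return arr


def _as_binary(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise DegenerateImageError(f"expected HxW binary array, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise KiwigradeError(f"binary image may only contain {{0, 255}}, found {vals[:5]}")
    return arr


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """NTSC luma conversion, gray = 0.299 R + 0.587 G + 0.114 B.

    Each output pixel is rounded half-up to the nearest integer and clamped
    to [0, 255]; output dtype is uint8.
    """
    arr = _as_rgb(img).astype(np.float64)
    wr, wg, wb = _NTSC_WEIGHTS
    gray = wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]
    # round-half-up, then clamp
    gray = np.floor(gray + 0.5)
    return np.clip(gray, 0, 255).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's global threshold over the 256-bin histogram.

    Returns the threshold ``t`` minimizing the within-class sum of squared
    deviations of the two populations ``{pixel < t}`` and ``{pixel >= t}``
    (the convention :func:`binarize` uses). Ties are broken toward the lowest
    threshold. A constant image raises :class:`DegenerateImageError`.
    """
    g = _as_gray(img)
    counts = np.bincount(g.astype(np.int64).ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("constant image has no Otsu threshold")

    levels = np.arange(256, dtype=np.float64)
    c0 = np.cumsum(counts)
    c1 = np.cumsum(counts * levels)
    c2 = np.cumsum(counts * levels**2)

    # class 0 = pixels < t, for t = 0..255
    n0 = np.concatenate(([0.0], c0[:-1]))
    s1 = np.concatenate(([0.0], c1[:-1]))
    s2 = np.concatenate(([0.0], c2[:-1]))
    n1 = c0[-1] - n0
    t1 = c1[-1] - s1
    t2 = c2[-1] - s2

    ss0 = np.where(n0 > 0, s2 - s1**2 / np.maximum(n0, 1.0), 0.0)
    ss1 = np.where(n1 > 0, t2 - t1**2 / np.maximum(n1, 1.0), 0.0)
    within = ss0 + ss1
    return int(np.argmin(within))  # argmin takes the first (lowest) minimizer


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Threshold a gray image: pixel < threshold -> 0, pixel >= threshold -> 255."""
    if not (0 <= threshold <= 255):
        raise KiwigradeError(f"threshold must lie in [0, 255], got {threshold}")
    g = _as_gray(img)
    return np.where(g >= threshold, 255, 0).astype(np.uint8)


def _label_components(binary: np.ndarray, connectivity: int) -> tuple[np.ndarray, np.ndarray]:
    labels = _cc_label(binary > 0, connectivity=connectivity)
    sizes = np.bincount(labels.ravel())
    if labels.max() == 0:
        raise EmptyForegroundError("binary image has no white pixels")
    return labels, sizes


def remove_small_regions(
    img: np.ndarray, connectivity: int = 2, min_area_fraction: float = 1.0 / 20.0
) -> np.ndarray:
    """Drop white components strictly smaller than a fraction of the largest.

    The default fraction is 1/20; a component whose area equals exactly
    max_area/20 is kept ("smaller than" is strict). The largest component
    always survives.
    """
    cleaned, _ = _remove_small_regions_counted(img, connectivity, min_area_fraction)
    return cleaned


def _remove_small_regions_counted(
    img: np.ndarray, connectivity: int = 2, min_area_fraction: float = 1.0 / 20.0
) -> tuple[np.ndarray, int]:
    binary = _as_binary(img)
    labels, sizes = _label_components(binary, connectivity)
    max_area = sizes[1:].max()
    cutoff = max_area * min_area_fraction
    keep = np.ones_like(sizes, dtype=bool)
    keep[0] = False
    keep[1:] = sizes[1:] >= cutoff
    n_removed = int(np.count_nonzero(~keep[1:]))
    cleaned = np.where(keep[labels], 255, 0).astype(np.uint8)
    return cleaned, n_removed


def min_bounding_rect(img: np.ndarray) -> PixelMeasurement:
    """Axis-aligned minimal bounding rectangle and white-pixel count.

    ``pl`` is the longer side of the rectangle (length direction by the
    long-side convention), ``pw`` the shorter side, ``ppa`` the total number
    of white pixels.
    """
    binary = _as_binary(img)
    rows, cols = np.nonzero(binary)
    if rows.size == 0:
        raise EmptyForegroundError("binary image has no white pixels")
    extent_y = int(rows.max() - rows.min() + 1)
    extent_x = int(cols.max() - cols.min() + 1)
    return PixelMeasurement(
        pl=max(extent_x, extent_y),
        pw=min(extent_x, extent_y),
        ppa=int(rows.size),
    )


def _profile_spacing(profile: np.ndarray) -> float:
    """Mean spacing of dark grid lines along a 1-D intensity profile."""
    x = np.asarray(profile, dtype=np.float64)
    depth = np.median(x) - x  # grid lines are darker than the paper
    if depth.max() <= 0:
        raise CalibrationError("no grid lines found in intensity profile")
    peaks, _ = find_peaks(depth, prominence=0.5 * depth.max())
    if len(peaks) < 2:
        raise CalibrationError("fewer than two grid lines detected")
    # least-squares slope of peak position vs peak index: robust to the
    # +-0.5 px quantization of line positions at fractional pitches
    return float(np.polyfit(np.arange(len(peaks)), peaks, 1)[0])


def calibrate(grid_img: np.ndarray, grid_pitch_mm: float = 1.0) -> Calibration:
    """Estimate the calibration ratio RA from a coordinate-paper image.

    Grid lines are located as periodic dark minima of the row- and
    column-mean intensity profiles; the mean line spacing divided by the
    physical pitch gives pixels per mm, and RA = (px per mm)^2.
    """
    if grid_pitch_mm <= 0:
        raise CalibrationError("grid pitch must be positive")
    g = _as_gray(grid_img).astype(np.float64)
    col_spacing = _profile_spacing(g.mean(axis=0))
    row_spacing = _profile_spacing(g.mean(axis=1))
    px_per_mm = 0.5 * (col_spacing + row_spacing) / grid_pitch_mm
    return Calibration(ra=px_per_mm**2)


def to_physical(
    pm: PixelMeasurement,
    cal: Calibration,
    weight_g: float,
    hair_offset_mm: float = 0.0,
) -> FruitMeasurement:
    """Convert pixel sizes to physical units through the calibration ratio.

    L = PL/sqrt(RA), MaDES = PW/sqrt(RA), PA = PPA/RA; the weight is passed
    through unchanged. ``hair_offset_mm`` (default 0) is subtracted from both
    linear sizes to compensate for the hair fringe.
    """
    s = cal.px_per_mm
    return FruitMeasurement(
        weight_g=weight_g,
        length_mm=pm.pl / s - hair_offset_mm,
        mades_mm=pm.pw / s - hair_offset_mm,
        pa_mm2=pm.ppa / cal.ra,
    )


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def _auto_calibration(gray: np.ndarray, config: PipelineConfig) -> Calibration:
    """Detect RA from the top border strip, which shows bare coordinate paper."""
    strip_h = max(12, int(round(config.calibration_border_frac * gray.shape[0])))
    strip = gray[:strip_h, :]
    px_col = _profile_spacing(strip.astype(np.float64).mean(axis=0))
    px_row = _profile_spacing(strip.astype(np.float64).mean(axis=1))
    px_per_mm = 0.5 * (px_col + px_row) / config.grid_pitch_mm
    return Calibration(ra=px_per_mm**2)


def measure_image(
    rgb: np.ndarray,
    weight_g: float,
    config: PipelineConfig | None = None,
    calibration: Calibration | None = None,
) -> MeasurementResult:
    """Run the full measurement chain on one RGB fruit image.

    Calibration precedence: an explicit ``calibration`` argument, then
    ``config.ra``, then automatic grid detection on the image border.
    """
    config = config or PipelineConfig()
    gray = rgb_to_gray(rgb)
    if calibration is None:
        if config.ra is not None:
            calibration = Calibration(ra=config.ra)
        else:
            calibration = _auto_calibration(gray, config)
    threshold = otsu_threshold(gray)
    binary = binarize(gray, threshold)
    if config.invert:
        binary = (255 - binary).astype(np.uint8)
    cleaned, n_removed = _remove_small_regions_counted(
        binary, config.connectivity, config.min_area_fraction
    )
    pixels = min_bounding_rect(cleaned)
    fruit = to_physical(pixels, calibration, weight_g, config.hair_offset_mm)
    return MeasurementResult(
        fruit=fruit,
        pixels=pixels,
        calibration=calibration,
        threshold=threshold,
        n_components_removed=n_removed,
    )
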