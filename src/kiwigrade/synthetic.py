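"""Synthetic fruit images and populations with known ground truth.

Two generators make every pipeline stage testable without real data:

* :func:`render_fruit` draws a single fruit silhouette — a rotated
  superellipse with an outward sinusoidal "hair" fringe — on a 1 mm
  coordinate-grid background, with additive Gaussian pixel noise and optional
  small noise blobs. Ground-truth length, MaDES and projected area are
  computed from the continuous boundary curve, so pipeline errors can be
  measured exactly.

* :func:`sample_population` draws per-class morphometric populations
  (weight, length, MaDES, MiDES, PA, volume) whose marginal moments default
  to the published 'Hayward' reference statistics, including a "flattened"
  subpopulation (heavy, wide, low MMR) that reproduces the characteristic
  overgrading confusion structure.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gamma as _gamma

from .errors import SyntheticSpecError
from .grading import GradeClass, assign_class
from .reference import CLASS_MOMENTS, VARIABLES, ClassMoments

__all__ = [
    "SyntheticFruitSpec",
    "PopulationSpec",
    "ValidationFixture",
    "render_grid",
    "render_fruit",
    "superellipse_area_fraction",
    "exponent_for_area_fraction",
    "sample_population",
    "make_validation_fixture",
]


# ---------------------------------------------------------------------------
# superellipse geometry
# ---------------------------------------------------------------------------

def superellipse_area_fraction(exponent: float) -> float:
    """Area of |x/a|^n + |y/b|^n <= 1 as a fraction of the 2a x 2b box.

    n = 2 gives pi/4 ~= 0.785 (an ellipse); the fraction grows toward 1 as
    the shape squares off. Real kiwifruit silhouettes correspond to n ~ 5
    (PA/(L*MaDES) ~ 0.95 in the reference population).
    """
    if exponent < 2:
        raise SyntheticSpecError(f"superellipse exponent must be >= 2, got {exponent}")
    n = exponent
    return float(_gamma(1 + 1 / n) ** 2 / _gamma(1 + 2 / n))


def exponent_for_area_fraction(fraction: float) -> float:
    """Invert :func:`superellipse_area_fraction` on n in [2, 12] (clamped)."""
    lo, hi = superellipse_area_fraction(2.0), superellipse_area_fraction(12.0)
    f = float(np.clip(fraction, lo, hi))
    if f <= lo:
        return 2.0
    if f >= hi:
        return 12.0
    return float(brentq(lambda n: superellipse_area_fraction(n) - f, 2.0, 12.0))


# ---------------------------------------------------------------------------
# single-fruit renderer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFruitSpec:
    """Geometry and imaging parameters for one rendered fruit.

    Lengths are in mm; ``ra`` is pixels per mm^2. The hair fringe is an
    outward-only boundary perturbation of amplitude ``hair_amplitude_mm``
    oscillating at ``hair_frequency_per_deg`` cycles per degree, so the
    silhouette oversizes each linear dimension by up to one amplitude per
    side — mirroring the hair-induced bias of real images. Foreground and
    background gray levels must be at least 3 noise SDs apart.
    """

    semi_axis_long_mm: float = 33.0
    semi_axis_short_mm: float = 27.0
    exponent: float = 5.0
    hair_amplitude_mm: float = 0.3
    hair_frequency_per_deg: float = 0.5
    rotation_deg: float = 0.0
    ra: float = 25.0
    noise_blob_count: int = 0
    noise_blob_radius_px: tuple[int, int] = (2, 5)
    background_level: float = 70.0
    grid_level: float = 45.0
    foreground_level: float = 200.0
    noise_sd: float = 5.0
    grid_pitch_mm: float = 1.0
    margin_mm: float = 8.0
    canvas_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.semi_axis_long_mm >= self.semi_axis_short_mm > 0):
            raise SyntheticSpecError("need semi_axis_long >= semi_axis_short > 0")
        if self.exponent < 2:
            raise SyntheticSpecError("superellipse exponent must be >= 2")
        if self.hair_amplitude_mm < 0 or self.hair_frequency_per_deg <= 0:
            raise SyntheticSpecError("invalid hair parameters")
        if self.ra <= 0:
            raise SyntheticSpecError("ra must be positive")
        if abs(self.foreground_level - self.background_level) < 3 * self.noise_sd:
            raise SyntheticSpecError(
                "foreground/background separation must be at least 3 noise SDs"
            )


def render_grid(
    shape: tuple[int, int],
    ra: float,
    grid_pitch_mm: float = 1.0,
    background_level: float = 70.0,
    line_level: float = 45.0,
) -> np.ndarray:
    """Coordinate-paper background: dark 1 px lines every pitch, float canvas."""
    h, w = shape
    canvas = np.full((h, w), float(background_level))
    pitch_px = grid_pitch_mm * np.sqrt(ra)
    for dim, axis in ((h, 0), (w, 1)):
        ks = np.arange(int(np.floor((dim - 1) / pitch_px)) + 1)
        pos = np.round(ks * pitch_px).astype(int)
        pos = pos[pos < dim]
        if axis == 0:
            canvas[pos, :] = line_level
        else:
            canvas[:, pos] = line_level
    return canvas


def _boundary_radius(spec: SyntheticFruitSpec, theta: np.ndarray, phase: float) -> np.ndarray:
    """Radius of the hairy superellipse boundary at polar angles ``theta``."""
    a, b, n = spec.semi_axis_long_mm, spec.semi_axis_short_mm, spec.exponent
    base = (np.abs(np.cos(theta) / a) ** n + np.abs(np.sin(theta) / b) ** n) ** (-1.0 / n)
    h = spec.hair_amplitude_mm
    if h > 0:
        theta_deg = np.degrees(theta)
        hair = h * 0.5 * (1.0 + np.sin(2 * np.pi * spec.hair_frequency_per_deg * theta_deg + phase))
    else:
        hair = 0.0
    return base + hair


def _ground_truth(spec: SyntheticFruitSpec, phase: float) -> dict[str, float]:
    theta = np.linspace(0.0, 2 * np.pi, 36001)
    r = _boundary_radius(spec, theta, phase)
    rot = np.radians(spec.rotation_deg)
    x = r * np.cos(theta + rot)
    y = r * np.sin(theta + rot)
    ext_x = float(x.max() - x.min())
    ext_y = float(y.max() - y.min())
    pa = float(0.5 * np.trapezoid(r**2, theta))
    return {
        "length_mm": max(ext_x, ext_y),
        "mades_mm": min(ext_x, ext_y),
        "pa_mm2": pa,
    }


def render_fruit(
    spec: SyntheticFruitSpec, seed: int
) -> tuple[np.ndarray, dict[str, float]]:
    """Render one fruit image; returns (uint8 RGB array, ground-truth dict).

    Ground truth (length, MaDES, PA) is computed from the continuous boundary
    curve, including the hair fringe, before pixel discretization.
    """
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 2 * np.pi))
    truth = _ground_truth(spec, phase)

    s = 1.0 / np.sqrt(spec.ra)  # mm per pixel
    reach = spec.semi_axis_long_mm + spec.hair_amplitude_mm
    if spec.canvas_mm is not None:
        w_mm, h_mm = spec.canvas_mm
        if 2 * reach > min(w_mm, h_mm):
            raise SyntheticSpecError("fruit (with hair) does not fit the requested canvas")
    else:
        w_mm = truth["length_mm"] + 2 * spec.margin_mm
        h_mm = truth["length_mm"] + 2 * spec.margin_mm
    w_px = int(np.ceil(w_mm / s))
    h_px = int(np.ceil(h_mm / s))

    canvas = render_grid(
        (h_px, w_px), spec.ra, spec.grid_pitch_mm, spec.background_level, spec.grid_level
    )

    # pixel-center coordinates in mm, origin at canvas center
    jj, ii = np.meshgrid(np.arange(w_px), np.arange(h_px))
    x_mm = (jj + 0.5 - w_px / 2.0) * s
    y_mm = (ii + 0.5 - h_px / 2.0) * s
    rot = np.radians(spec.rotation_deg)
    xr = np.cos(rot) * x_mm + np.sin(rot) * y_mm
    yr = -np.sin(rot) * x_mm + np.cos(rot) * y_mm
    theta = np.mod(np.arctan2(yr, xr), 2 * np.pi)
    rho = np.hypot(xr, yr)

    theta_grid = np.linspace(0.0, 2 * np.pi, 36001)
    r_grid = _boundary_radius(spec, theta_grid, phase)
    mask = rho <= np.interp(theta, theta_grid, r_grid)
    canvas[mask] = spec.foreground_level

    # small bright noise blobs outside the fruit
    r_max_px = (reach / s) + 3
    for _ in range(spec.noise_blob_count):
        for _attempt in range(100):
            ci = rng.integers(0, h_px)
            cj = rng.integers(0, w_px)
            rad = int(rng.integers(spec.noise_blob_radius_px[0], spec.noise_blob_radius_px[1] + 1))
            d = np.hypot(ci - h_px / 2.0, cj - w_px / 2.0)
            if d > r_max_px + rad:
                blob = (ii - ci) ** 2 + (jj - cj) ** 2 <= rad**2
                canvas[blob] = spec.foreground_level
                break

    canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    gray = np.clip(np.round(canvas), 0, 255)

    # mild channel tinting (fruit scenes are greenish); luma stays ~ gray
    rgb = np.stack(
        [
            np.clip(np.round(gray * 0.92), 0, 255),
            np.clip(np.round(gray * 1.08), 0, 255),
            np.clip(np.round(gray * 0.90), 0, 255),
        ],
        axis=-1,
    ).astype(np.uint8)
    return rgb, truth


# ---------------------------------------------------------------------------
# population sampler
# ---------------------------------------------------------------------------

#: Default correlation among (weight, length, MaDES, MiDES). Sizes of a
#: fruit co-vary strongly; corr(L, MaDES) = 0.93 and corr(MaDES, MiDES) =
#: 0.90 reproduce the published within-class spreads of the length/MaDES
#: ratio (~0.05) and of the MMR (~0.05) respectively.
DEFAULT_CORRELATION = np.array(
    [
        [1.00, 0.85, 0.85, 0.80],
        [0.85, 1.00, 0.93, 0.85],
        [0.85, 0.93, 1.00, 0.90],
        [0.80, 0.85, 0.90, 1.00],
    ]
)

#: Moments of the flattened class II subpopulation: heavy, wide, thin fruit
#: whose MMR falls below 0.7 despite weights over 90 g. Their minimum
#: diameter sits well below the pooled linear MiDES trend for their weight
#: and length, so the estimator overpredicts it — the mechanism behind
#: class II fruit being overgraded into class I.
FLATTENED_MOMENTS = ClassMoments(
    n=0,
    mean={
        "weight_g": 100.0,
        "length_mm": 62.0,
        "mades_mm": 60.0,
        "mides_mm": 41.0,
        "pa_cm2": 35.5,
        "volume_cm3": 85.0,
    },
    sd={
        "weight_g": 8.0,
        "length_mm": 4.0,
        "mades_mm": 4.0,
        "mides_mm": 1.8,
        "pa_cm2": 4.0,
        "volume_cm3": 9.0,
    },
)

#: Moments of the mildly flattened class I subpopulation: fruit heavy enough
#: for Extra (weight over 90 g) held back by an MMR between 0.7 and 0.8.
#: Their relatively large MaDES gives them a distinctly lower length/MaDES
#: ratio than true Extra fruit — the separation the ratio-plane
#: reclassification exploits.
SEMI_FLATTENED_MOMENTS = ClassMoments(
    n=0,
    mean={
        "weight_g": 102.0,
        "length_mm": 67.0,
        "mades_mm": 56.5,
        "mides_mm": 44.0,
        "pa_cm2": 36.5,
        "volume_cm3": 90.0,
    },
    sd={
        "weight_g": 8.0,
        "length_mm": 4.0,
        "mades_mm": 3.0,
        "mides_mm": 1.5,
        "pa_cm2": 4.0,
        "volume_cm3": 10.0,
    },
)

#: Regular (well-formed) class I fruit: normally shaped but too light for
#: Extra. Mixed 69/31 with the semi-flattened morph, the class marginals
#: approximate the published class I row.
CLASS_I_REGULAR_MOMENTS = ClassMoments(
    n=0,
    mean={
        "weight_g": 82.0,
        "length_mm": 62.0,
        "mades_mm": 51.0,
        "mides_mm": 44.1,
        "pa_cm2": 29.0,
        "volume_cm3": 84.0,
    },
    sd={
        "weight_g": 8.0,
        "length_mm": 4.5,
        "mades_mm": 4.0,
        "mides_mm": 2.2,
        "pa_cm2": 4.0,
        "volume_cm3": 12.0,
    },
)

#: Regular class II fruit: well-formed but in the 65-70 g weight band, so
#: class II purely on weight. Mixed 80/20 with the flattened morph.
CLASS_II_REGULAR_MOMENTS = ClassMoments(
    n=0,
    mean={
        "weight_g": 67.5,
        "length_mm": 59.0,
        "mades_mm": 49.5,
        "mides_mm": 42.9,
        "pa_cm2": 27.0,
        "volume_cm3": 75.0,
    },
    sd={
        "weight_g": 1.4,
        "length_mm": 4.6,
        "mades_mm": 3.5,
        "mides_mm": 3.1,
        "pa_cm2": 4.0,
        "volume_cm3": 8.0,
    },
)


@dataclass(frozen=True)
class PopulationSpec:
    """Per-class sampling specification for a synthetic fruit population.

    ``classes`` maps grade class (or the string ``"Total"``) to marginal
    moments; defaults are the published reference statistics and set the
    per-class sample counts. ``correlation`` is the latent Gaussian
    correlation among (weight, length, MaDES, MiDES); PA and volume are
    derived from L*MaDES and L*MaDES*MiDES products with multiplicative
    noise, then standardized to the class marginal moments.

    Classes I and II are drawn as two-morph mixtures: a regular morph plus a
    (semi-)flattened one whose low MMR at high weight reproduces the
    characteristic overgrading confusion of MMR-from-estimated-MiDES grading.
    The default sub-moments are calibrated so the mixtures approximate the
    published class rows.
    """

    classes: Mapping = None  # type: ignore[assignment]
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    flattened_fraction: float = 0.20
    flattened_moments: ClassMoments = FLATTENED_MOMENTS
    class_ii_regular_moments: ClassMoments = CLASS_II_REGULAR_MOMENTS
    semi_flattened_fraction: float = 0.31
    semi_flattened_moments: ClassMoments = SEMI_FLATTENED_MOMENTS
    class_i_regular_moments: ClassMoments = CLASS_I_REGULAR_MOMENTS
    shape_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes is None:
            object.__setattr__(self, "classes", dict(CLASS_MOMENTS))
        corr = np.asarray(self.correlation, dtype=np.float64)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise SyntheticSpecError("correlation must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise SyntheticSpecError("correlation matrix must be positive-definite")
        for frac in (self.flattened_fraction, self.semi_flattened_fraction):
            if not (0 <= frac <= 1):
                raise SyntheticSpecError("subpopulation fractions must lie in [0, 1]")
        for m in self.classes.values():
            if any(s < 0 for s in m.sd.values()):
                raise SyntheticSpecError("standard deviations must be non-negative")


_LATENT = ("weight_g", "length_mm", "mades_mm", "mides_mm")


def _standardize_to(raw: np.ndarray, mean: float, sd: float) -> np.ndarray:
    spread = raw.std()
    if spread == 0 or sd == 0:
        return np.full_like(raw, mean)
    return mean + sd * (raw - raw.mean()) / spread


def _sample_moments(
    rng: np.random.Generator,
    moments: ClassMoments,
    corr: np.ndarray,
    n: int,
    shape_noise: float,
) -> pd.DataFrame:
    chol = np.linalg.cholesky(corr)
    cols = {}
    z = rng.standard_normal((n, 4)) @ chol.T
    for k, name in enumerate(_LATENT):
        cols[name] = moments.mean[name] + moments.sd[name] * z[:, k]
    # redraw any row with a non-positive size (truncation to the positive orthant)
    vals = np.column_stack([cols[name] for name in _LATENT])
    bad = (vals <= 0).any(axis=1)
    for _ in range(100):
        if not bad.any():
            break
        z = rng.standard_normal((int(bad.sum()), 4)) @ chol.T
        for k, name in enumerate(_LATENT):
            vals[bad, k] = moments.mean[name] + moments.sd[name] * z[:, k]
        bad = (vals <= 0).any(axis=1)
    if bad.any():
        raise SyntheticSpecError("could not draw positive morphometrics; check moments")
    for k, name in enumerate(_LATENT):
        cols[name] = vals[:, k]

    pa_raw = cols["length_mm"] * cols["mades_mm"] * (1 + shape_noise * rng.standard_normal(n))
    vol_raw = (
        cols["length_mm"] * cols["mades_mm"] * cols["mides_mm"]
        * (1 + shape_noise * rng.standard_normal(n))
    )
    cols["pa_cm2"] = np.maximum(
        _standardize_to(pa_raw, moments.mean["pa_cm2"], moments.sd["pa_cm2"]), 1e-3
    )
    cols["volume_cm3"] = np.maximum(
        _standardize_to(vol_raw, moments.mean["volume_cm3"], moments.sd["volume_cm3"]), 1e-3
    )
    return pd.DataFrame(cols)


def _class_counts(spec: PopulationSpec, n_total: int | None) -> dict:
    base = {key: m.n for key, m in spec.classes.items()}
    if n_total is None:
        return base
    total = sum(base.values())
    raw = {k: n_total * v / total for k, v in base.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n_total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:remainder]:
        counts[k] += 1
    return counts


def sample_population(
    spec: PopulationSpec | None = None,
    n_total: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a synthetic fruit population table.

    Returns one row per fruit with columns ``weight_g, length_mm, mades_mm,
    mides_mm, pa_cm2, volume_cm3, source_class, actual_class``. The
    ``actual_class`` label is recomputed from the sampled weight and true MMR
    through the FFV-46 rule, so it may disagree with the ``source_class`` the
    moments were drawn from — that disagreement is deliberate and mirrors
    real populations straddling the grade boundaries.
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = _class_counts(spec, n_total)
    frames = []
    for key, n in counts.items():
        if n == 0:
            continue
        moments = spec.classes[key]
        if key == GradeClass.CLASS_II:
            sub_frac, sub_moments = spec.flattened_fraction, spec.flattened_moments
            moments = spec.class_ii_regular_moments
        elif key == GradeClass.CLASS_I:
            sub_frac, sub_moments = spec.semi_flattened_fraction, spec.semi_flattened_moments
            moments = spec.class_i_regular_moments
        else:
            sub_frac, sub_moments = 0.0, moments
        n_sub = int(round(sub_frac * n))
        parts = []
        if n - n_sub > 0:
            part = _sample_moments(rng, moments, spec.correlation, n - n_sub, spec.shape_noise)
            part["morph"] = "regular"
            parts.append(part)
        if n_sub > 0:
            part = _sample_moments(rng, sub_moments, spec.correlation, n_sub, spec.shape_noise)
            part["morph"] = "flattened"
            parts.append(part)
        frame = pd.concat(parts, ignore_index=True)
        frame["source_class"] = key.label if isinstance(key, GradeClass) else str(key)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table["actual_class"] = [
        assign_class(w, mi / ma).label
        for w, ma, mi in zip(table["weight_g"], table["mades_mm"], table["mides_mm"])
    ]
    return table


# ---------------------------------------------------------------------------
# end-to-end validation fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationFixture:
    """Rendered images plus the matching weight and ground-truth tables."""

    images: list[np.ndarray]
    specs: list[SyntheticFruitSpec]
    weights: pd.DataFrame  # image_id, weight_g
    truth: pd.DataFrame  # image_id + morphometrics + render truth + class


def _away_from_boundaries(row, mmr_margin: float, weight_margin: float) -> bool:
    mmr = row["mides_mm"] / row["mades_mm"]
    if any(abs(mmr - t) < mmr_margin for t in (0.7, 0.8)):
        return False
    if any(abs(row["weight_g"] - t) < weight_margin for t in (65.0, 70.0, 90.0)):
        return False
    return True


def make_validation_fixture(
    seed: int,
    n: int = 20,
    ra: float = 25.0,
    hair_amplitude_mm: float = 0.1,
    mmr_margin: float = 0.02,
    weight_margin: float = 2.0,
    out_dir: str | Path | None = None,
) -> ValidationFixture:
    """Generate an end-to-end fixture of N rendered fruit with ground truth.

    Fruit whose true weight or MMR falls within a small margin of a grade
    boundary are resampled, so the fixture's true classes are unambiguous
    under sub-pixel measurement error. Each fruit's superellipse exponent is
    solved from its sampled PA/(L*MaDES) ratio, making the rendered projected
    area consistent with the sampled one. When ``out_dir`` is given, PNG
    images and the two CSVs are written there.
    """
    rng = np.random.default_rng(seed)
    rows = []
    spec = PopulationSpec(seed=int(rng.integers(0, 2**31 - 1)))
    while len(rows) < n:
        batch = sample_population(spec, n_total=max(2 * n, 8),
                                  seed=int(rng.integers(0, 2**31 - 1)))
        for _, row in batch.iterrows():
            if _away_from_boundaries(row, mmr_margin, weight_margin):
                rows.append(row)
            if len(rows) == n:
                break
    table = pd.DataFrame(rows).reset_index(drop=True)

    images, specs, truth_rows = [], [], []
    for i, row in table.iterrows():
        frac = row["pa_cm2"] * 100.0 / (row["length_mm"] * row["mades_mm"])
        fruit_spec = SyntheticFruitSpec(
            semi_axis_long_mm=row["length_mm"] / 2.0,
            semi_axis_short_mm=row["mades_mm"] / 2.0,
            exponent=exponent_for_area_fraction(frac),
            hair_amplitude_mm=hair_amplitude_mm,
            ra=ra,
        )
        img, render_truth = render_fruit(fruit_spec, seed=int(rng.integers(0, 2**31 - 1)))
        images.append(img)
        specs.append(fruit_spec)
        truth_rows.append(
            {
                "image_id": f"fruit_{i:04d}",
                **{v: row[v] for v in VARIABLES},
                "render_length_mm": render_truth["length_mm"],
                "render_mades_mm": render_truth["mades_mm"],
                "render_pa_mm2": render_truth["pa_mm2"],
                "actual_class": row["actual_class"],
            }
        )
    truth = pd.DataFrame(truth_rows)
    weights = truth[["image_id", "weight_g"]].copy()

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row_id in zip(images, truth["image_id"]):
            iio.imwrite(out / f"{row_id}.png", img)
        weights.to_csv(out / "weights.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return ValidationFixture(images=images, specs=specs, weights=weights, truth=truth)
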