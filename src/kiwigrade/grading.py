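"""FFV-46 shape grading, confusion analysis, and ratio-space reclassification.

The UNECE FFV-46 marketing standard grades kiwifruit by weight and by the
ratio of the minimum to the maximum equatorial-section diameter (MMR):

    Extra:    weight >= 90 g and MMR >= 0.8
    class I:  weight >= 70 g and MMR >= 0.7
    class II: weight >= 65 g
    Reject:   everything else

When the MMR is formed from an *estimated* MiDES, estimation error misgrades
some fruit — mostly upward (overgrading), the economically costly direction.
This module provides the grade rule, confusion-table accounting of estimated
vs actual classes, and a reclassification step that re-examines fruit graded
Extra or class I using a linear discriminant in the (length/MaDES, length/PA)
ratio plane, where flattened fruit (low MMR at high weight) separate from
well-formed fruit.
"""

from __future__ import annotations

from dataclasses import dataclass
import enum
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import GradingError

__all__ = [
    "GradeClass",
    "GradeRule",
    "ConfusionTable",
    "DiscriminantLine",
    "assign_class",
    "build_confusion",
    "classification_rate",
    "overgrade_count",
    "reclassify",
    "fit_discriminant",
    "fit_reclassifier",
]


class GradeClass(enum.IntEnum):
    """Ordered grade classes; larger value means higher class."""

    REJECT = 0
    CLASS_II = 1
    CLASS_I = 2
    EXTRA = 3

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "GradeClass":
        try:
            return _FROM_LABEL[label.strip().lower()]
        except KeyError:
            raise GradingError(f"unknown grade label {label!r}") from None


_LABELS = {
    GradeClass.EXTRA: "Extra",
    GradeClass.CLASS_I: "I",
    GradeClass.CLASS_II: "II",
    GradeClass.REJECT: "Reject",
}
_FROM_LABEL = {
    "extra": GradeClass.EXTRA,
    "i": GradeClass.CLASS_I,
    "class i": GradeClass.CLASS_I,
    "ii": GradeClass.CLASS_II,
    "class ii": GradeClass.CLASS_II,
    "reject": GradeClass.REJECT,
}

#: Display order (highest class first), matching the standard's table layout.
CLASS_ORDER = (GradeClass.EXTRA, GradeClass.CLASS_I, GradeClass.CLASS_II, GradeClass.REJECT)


@dataclass(frozen=True)
class GradeRule:
    """Per-class minimum weight (g) and minimum MMR; both bounds inclusive.

    ``requirements`` lists (class, min_weight_g, min_mmr) from highest class
    downward; ``min_mmr`` is ``None`` when the class has no shape requirement.
    """

    requirements: tuple[tuple[GradeClass, float, float | None], ...] = (
        (GradeClass.EXTRA, 90.0, 0.8),
        (GradeClass.CLASS_I, 70.0, 0.7),
        (GradeClass.CLASS_II, 65.0, None),
    )

    def __post_init__(self) -> None:
        weights = [w for _, w, _ in self.requirements]
        if any(a <= b for a, b in zip(weights, weights[1:])):
            raise GradingError("weight thresholds must strictly decrease with class")
        mmrs = [m for _, _, m in self.requirements if m is not None]
        if any(a < b for a, b in zip(mmrs, mmrs[1:])):
            raise GradingError("MMR thresholds must be non-increasing with class")


FFV46_RULE = GradeRule()


def assign_class(weight_g: float, mmr: float, rule: GradeRule = FFV46_RULE) -> GradeClass:
    """First class (highest first) whose weight AND MMR requirements are met.

    Both thresholds are inclusive ("minimum weight", "0.8 or greater"); a
    fruit failing every class requirement is Reject.
    """
    if weight_g <= 0 or mmr <= 0:
        raise GradingError(f"weight and MMR must be positive, got {weight_g}, {mmr}")
    for cls, min_w, min_mmr in rule.requirements:
        if weight_g >= min_w and (min_mmr is None or mmr >= min_mmr):
            return cls
    return GradeClass.REJECT


# ---------------------------------------------------------------------------
# confusion accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """Counts of (estimated class x actual class).

    ``counts[i, j]`` is the number of fruit with estimated class
    ``CLASS_ORDER[i]`` and actual class ``CLASS_ORDER[j]``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (4, 4):
            raise GradingError(f"confusion table must be 4x4, got {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise GradingError("confusion cells must be non-negative integers")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_cells(
        cls, cells: Mapping[tuple[GradeClass, GradeClass], int]
    ) -> "ConfusionTable":
        arr = np.zeros((4, 4), dtype=np.int64)
        idx = {c: i for i, c in enumerate(CLASS_ORDER)}
        for (est, act), n in cells.items():
            arr[idx[est], idx[act]] += int(n)
        return cls(arr)

    def cell(self, estimated: GradeClass, actual: GradeClass) -> int:
        idx = {c: i for i, c in enumerate(CLASS_ORDER)}
        return int(self.counts[idx[estimated], idx[actual]])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_labels(self) -> tuple[list[GradeClass], list[GradeClass]]:
        """Expand the table back into (estimated, actual) label lists."""
        est, act = [], []
        for i, e in enumerate(CLASS_ORDER):
            for j, a in enumerate(CLASS_ORDER):
                est.extend([e] * int(self.counts[i, j]))
                act.extend([a] * int(self.counts[i, j]))
        return est, act

    def misgrade_rates_by_actual(self) -> dict[GradeClass, float]:
        """Percent of each actual class assigned any other class."""
        out = {}
        for j, actual in enumerate(CLASS_ORDER):
            col = self.counts[:, j]
            n = int(col.sum())
            if n == 0:
                continue
            wrong = n - int(col[j])
            out[actual] = 100.0 * wrong / n
        return out

    def report(self) -> str:
        head = "Estimated\\Actual " + " ".join(f"{c.label:>7}" for c in CLASS_ORDER)
        lines = [head]
        for i, e in enumerate(CLASS_ORDER):
            row = " ".join(f"{int(self.counts[i, j]):>7}" for j in range(4))
            lines.append(f"{e.label:<17} {row}")
        rate = classification_rate(self)
        n_over, pct_over = overgrade_count(self)
        lines.append(f"Correctly classified: {rate:.1f}% of {self.total}")
        lines.append(f"Overgraded: {n_over} ({pct_over:.1f}%)")
        return "\n".join(lines)


def build_confusion(
    estimated: Sequence[GradeClass], actual: Sequence[GradeClass]
) -> ConfusionTable:
    """Tabulate estimated-vs-actual class labels into a 4x4 confusion table."""
    if len(estimated) != len(actual):
        raise GradingError(
            f"label lists differ in length: {len(estimated)} vs {len(actual)}"
        )
    arr = np.zeros((4, 4), dtype=np.int64)
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    for e, a in zip(estimated, actual):
        arr[idx[GradeClass(e)], idx[GradeClass(a)]] += 1
    return ConfusionTable(arr)


def classification_rate(ct: ConfusionTable) -> float:
    """Percent of fruit on the diagonal (estimated class equals actual)."""
    if ct.total == 0:
        raise GradingError("cannot compute a rate on an empty table")
    return 100.0 * float(np.trace(ct.counts)) / ct.total


def overgrade_count(ct: ConfusionTable) -> tuple[int, float]:
    """Number and percent of fruit whose estimated class exceeds the actual one."""
    if ct.total == 0:
        raise GradingError("cannot compute a rate on an empty table")
    n = 0
    for i, est in enumerate(CLASS_ORDER):
        for j, act in enumerate(CLASS_ORDER):
            if est > act:
                n += int(ct.counts[i, j])
    return n, 100.0 * n / ct.total


# ---------------------------------------------------------------------------
# ratio-space reclassification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminantLine:
    """An oriented line a*x + b*y + c = 0 in the (length/MaDES, length/PA) plane.

    ``pos_class``/``neg_class`` name the grade assigned on the positive /
    negative side of the line; either may be ``None`` meaning "defer to the
    next line of the context". A point exactly on the line is assigned the
    lower of the two side classes (conservative grading) — or deferred if
    either side defers.
    """

    a: float
    b: float
    c: float
    pos_class: GradeClass | None
    neg_class: GradeClass | None

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise GradingError("discriminant line parameters must be finite")
        if self.a == 0 and self.b == 0:
            raise GradingError("degenerate discriminant line (a = b = 0)")

    @classmethod
    def from_slope_intercept(
        cls,
        slope: float,
        intercept: float,
        above_class: GradeClass | None,
        below_class: GradeClass | None,
    ) -> "DiscriminantLine":
        # y = slope*x + intercept  ->  -slope*x + y - intercept = 0,
        # positive side is above the line.
        return cls(a=-slope, b=1.0, c=-intercept, pos_class=above_class, neg_class=below_class)

    @property
    def slope(self) -> float:
        if self.b == 0:
            raise GradingError("vertical line has no finite slope")
        return -self.a / self.b

    @property
    def intercept(self) -> float:
        if self.b == 0:
            raise GradingError("vertical line has no intercept form")
        return -self.c / self.b

    def side(self, point: tuple[float, float]) -> float:
        x, y = point
        return self.a * x + self.b * y + self.c

    def decide(self, point: tuple[float, float]) -> GradeClass | None:
        s = self.side(point)
        if s > 0:
            return self.pos_class
        if s < 0:
            return self.neg_class
        # exactly on the line: conservative (lower class); defer if either defers
        if self.pos_class is None or self.neg_class is None:
            return None
        return min(self.pos_class, self.neg_class)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "pos_class": self.pos_class.label if self.pos_class is not None else None,
            "neg_class": self.neg_class.label if self.neg_class is not None else None,
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "DiscriminantLine":
        def _cls(v):
            return None if v is None else GradeClass.from_label(v)

        if "slope" in obj:
            return cls.from_slope_intercept(
                float(obj["slope"]),
                float(obj["intercept"]),
                _cls(obj.get("upper_class")),
                _cls(obj.get("lower_class")),
            )
        return cls(
            a=float(obj["a"]),
            b=float(obj["b"]),
            c=float(obj["c"]),
            pos_class=_cls(obj.get("pos_class")),
            neg_class=_cls(obj.get("neg_class")),
        )


#: Reclassifier configuration: context (estimated class) -> ordered line list.
LineConfig = Mapping[GradeClass, Sequence[DiscriminantLine]]


def lines_to_json(config: LineConfig) -> str:
    return json.dumps(
        {ctx.label: [ln.to_dict() for ln in lines] for ctx, lines in config.items()},
        indent=2,
    )


def lines_from_json(text: str) -> dict[GradeClass, list[DiscriminantLine]]:
    obj = json.loads(text)
    return {
        GradeClass.from_label(ctx): [DiscriminantLine.from_dict(d) for d in lines]
        for ctx, lines in obj.items()
    }


def reclassify(
    point: tuple[float, float],
    context: GradeClass,
    lines: LineConfig,
) -> GradeClass:
    """Re-grade one fruit from its (length/MaDES, length/PA) ratio point.

    Only fruit initially graded Extra or class I are re-examined; estimated
    class II and Reject pass through unchanged. The context's lines are
    evaluated in order; the first line that resolves a class decides.
    """
    context = GradeClass(context)
    if context in (GradeClass.CLASS_II, GradeClass.REJECT):
        return context
    ctx_lines = lines.get(context)
    if not ctx_lines:
        raise GradingError(f"no discriminant lines configured for context {context.label!r}")
    for line in ctx_lines:
        decided = line.decide(point)
        if decided is not None:
            return decided
    raise GradingError(
        f"discriminant lines for context {context.label!r} did not resolve a class"
    )


def fit_discriminant(
    points: Sequence[tuple[float, float]] | np.ndarray,
    labels: Sequence[GradeClass | None],
    pos_class: GradeClass | None = None,
    neg_class: GradeClass | None = None,
) -> DiscriminantLine:
    """Fit an equal-covariance two-class linear discriminant boundary.

    ``labels`` must contain exactly two distinct values (``None`` is allowed
    as a "defer" label); the returned line's positive side carries the class
    with the larger discriminant score. ``pos_class``/``neg_class`` override
    the side classes when given (useful to build deferring lines).
    """
    pts = np.asarray(points, dtype=np.float64)
    labs = list(labels)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GradingError(f"points must be n x 2, got shape {pts.shape}")
    uniq = sorted({l for l in labs}, key=lambda v: (-1 if v is None else int(v)))
    if len(uniq) != 2:
        raise GradingError(f"need exactly two classes, got {uniq}")
    y = np.array([uniq.index(l) for l in labs])
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise GradingError("need at least 2 points per group")
    if np.allclose(pts[y == 0].mean(axis=0), pts[y == 1].mean(axis=0)):
        raise GradingError("group means coincide; no discriminant direction")
    try:
        # empirical priors: the boundary is the error-minimizing Bayes rule
        # for the training groups, so reclassification never trades many
        # majority-group fruit for a few minority-group recoveries
        lda = LinearDiscriminantAnalysis(solver="svd").fit(pts, y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise GradingError(f"degenerate point configuration: {exc}") from None
    a, b = (float(v) for v in lda.coef_[0])
    c = float(lda.intercept_[0])
    if a == 0.0 and b == 0.0:
        raise GradingError("degenerate point configuration: zero discriminant")
    # decision_function > 0 corresponds to class index 1 (uniq[1])
    pos = uniq[1] if pos_class is None else pos_class
    neg = uniq[0] if neg_class is None else neg_class
    return DiscriminantLine(a=a, b=b, c=c, pos_class=pos, neg_class=neg)


def fit_reclassifier(
    points: np.ndarray,
    estimated: Sequence[GradeClass],
    actual: Sequence[GradeClass],
) -> dict[GradeClass, list[DiscriminantLine]]:
    """Fit the full reclassification configuration from labeled ratio points.

    Within estimated Extra, one line separates actual Extra from actual
    class I. Within estimated class I, a first line splits off actual class
    II and a second separates actual Extra from actual class I. Contexts or
    lines whose training groups are too small are omitted.
    """
    pts = np.asarray(points, dtype=np.float64)
    est = np.array([int(e) for e in estimated])
    act = np.array([int(a) for a in actual])
    config: dict[GradeClass, list[DiscriminantLine]] = {}

    def _subset(mask, classes):
        m = mask & np.isin(act, [int(c) for c in classes])
        return pts[m], [GradeClass(a) for a in act[m]]

    # estimated Extra: Extra vs I
    p, l = _subset(est == int(GradeClass.EXTRA), (GradeClass.EXTRA, GradeClass.CLASS_I))
    if len({*l}) == 2 and min(l.count(GradeClass.EXTRA), l.count(GradeClass.CLASS_I)) >= 2:
        config[GradeClass.EXTRA] = [fit_discriminant(p, l)]

    # estimated class I: first II vs rest (deferring), then Extra vs I
    mask = est == int(GradeClass.CLASS_I)
    lines: list[DiscriminantLine] = []
    p_all = pts[mask]
    l_all = [GradeClass(a) for a in act[mask]]
    n_ii = l_all.count(GradeClass.CLASS_II)
    if n_ii >= 2 and len(l_all) - n_ii >= 2:
        merged = [
            GradeClass.CLASS_II if a == GradeClass.CLASS_II else None for a in l_all
        ]
        lines.append(fit_discriminant(p_all, merged))
    p, l = _subset(mask, (GradeClass.EXTRA, GradeClass.CLASS_I))
    if len({*l}) == 2 and min(l.count(GradeClass.EXTRA), l.count(GradeClass.CLASS_I)) >= 2:
        lines.append(fit_discriminant(p, l))
    elif l:
        # single class present: terminal line not fittable; fall back to identity
        lines.append(
            DiscriminantLine(a=0.0, b=1.0, c=0.0, pos_class=l[0], neg_class=l[0])
        )
    if lines:
        config[GradeClass.CLASS_I] = lines
    return config


def reclassify_all(
    points: Iterable[tuple[float, float]],
    estimated: Sequence[GradeClass],
    lines: LineConfig,
) -> list[GradeClass]:
    """Vector form of :func:`reclassify`; contexts without configured lines
    pass through unchanged."""
    out = []
    for point, ctx in zip(points, estimated):
        ctx = GradeClass(ctx)
        if ctx in lines and lines[ctx]:
            out.append(reclassify(point, ctx, lines))
        else:
            out.append(ctx)
    return out
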