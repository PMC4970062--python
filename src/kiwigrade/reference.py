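"""Published reference statistics for 'Hayward' kiwifruit shape grading.

These are the summary statistics of a 490-fruit 'Hayward' reference
population graded under UNECE FFV-46, used throughout the package as inputs:
per-class morphometric moments parameterize the synthetic population
generator, and the published estimated-vs-actual confusion counts (350
validation fruit) drive the confusion-rate and reclassification arithmetic.

Variables, with units:
    weight_g     fruit weight (g)
    length_mm    fruit length (mm)
    mades_mm     maximum equatorial-section diameter (mm)
    mides_mm     minimum equatorial-section diameter (mm)
    pa_cm2       projected area (cm^2)
    volume_cm3   volume (cm^3)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .grading import ConfusionTable, GradeClass, build_confusion

__all__ = [
    "VARIABLES",
    "ClassMoments",
    "CLASS_MOMENTS",
    "TOTAL_MOMENTS",
    "CONFUSION_CELLS",
    "published_confusion_table",
    "apply_reported_reclassification",
]

VARIABLES = ("weight_g", "length_mm", "mades_mm", "mides_mm", "pa_cm2", "volume_cm3")


@dataclass(frozen=True)
class ClassMoments:
    """Sample size and marginal mean/SD of each morphometric variable."""

    n: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]


def _moments(n, w, l, ma, mi, pa, v, sw, sl, sma, smi, spa, sv) -> ClassMoments:
    return ClassMoments(
        n=n,
        mean={
            "weight_g": w,
            "length_mm": l,
            "mades_mm": ma,
            "mides_mm": mi,
            "pa_cm2": pa,
            "volume_cm3": v,
        },
        sd={
            "weight_g": sw,
            "length_mm": sl,
            "mades_mm": sma,
            "mides_mm": smi,
            "pa_cm2": spa,
            "volume_cm3": sv,
        },
    )


#: Per-class marginal moments of the reference population.
CLASS_MOMENTS: dict[GradeClass, ClassMoments] = {
    GradeClass.EXTRA: _moments(163, 113.0, 70.9, 56.9, 49.9, 37.8, 108.7,
                               15.0, 7.5, 6.6, 7.0, 4.4, 14.9),
    GradeClass.CLASS_I: _moments(157, 90.7, 63.6, 52.4, 44.1, 31.7, 86.5,
                                 19.0, 4.7, 5.3, 2.2, 5.8, 18.5),
    GradeClass.CLASS_II: _moments(133, 80.8, 59.4, 51.4, 42.5, 29.1, 77.5,
                                  28.2, 4.6, 10.6, 3.1, 9.1, 27.1),
    GradeClass.REJECT: _moments(37, 64.0, 58.8, 47.1, 41.4, 24.3, 61.8,
                                0.7, 2.6, 3.3, 3.4, 0.7, 2.4),
}

#: Whole-population marginal moments (all 490 fruit).
TOTAL_MOMENTS = _moments(490, 97.9, 65.9, 54.1, 46.2, 33.7, 93.9,
                         23.6, 7.5, 7.5, 5.8, 7.0, 22.9)

#: Published (estimated class, actual class) counts for the 350 validation fruit.
CONFUSION_CELLS: dict[tuple[GradeClass, GradeClass], int] = {
    (GradeClass.EXTRA, GradeClass.EXTRA): 103,
    (GradeClass.EXTRA, GradeClass.CLASS_I): 28,
    (GradeClass.CLASS_I, GradeClass.EXTRA): 13,
    (GradeClass.CLASS_I, GradeClass.CLASS_I): 85,
    (GradeClass.CLASS_I, GradeClass.CLASS_II): 13,
    (GradeClass.CLASS_II, GradeClass.CLASS_II): 82,
    (GradeClass.REJECT, GradeClass.REJECT): 26,
}


def published_confusion_table() -> ConfusionTable:
    """The published estimated-vs-actual confusion table (350 fruit)."""
    return ConfusionTable.from_cells(CONFUSION_CELLS)


def apply_reported_reclassification(ct: ConfusionTable | None = None) -> ConfusionTable:
    """Apply the reported ratio-discriminant reclassification outcome.

    The reference study re-examined fruit graded Extra or class I in the
    (length/MaDES, length/PA) ratio plane. The reported outcome, applied at
    the level of confusion-table cells:

    * estimated Extra: the discriminant separates the actual class I fruit
      (all 28 move to class I) but also sends 4 actual Extra fruit with them;
    * estimated class I: all 13 actual class II fruit and all 13 actual Extra
      fruit are separated to their own classes, while 2 actual class I fruit
      are grouped with the Extra side.

    Fruit graded class II or Reject are untouched. Starting from the
    published table this leaves 6 misclassified fruit out of 350.
    """
    if ct is None:
        ct = published_confusion_table()
    est, act = ct.to_labels()
    moves = {
        # (context, actual): (n_to_move, destination)
        (GradeClass.EXTRA, GradeClass.CLASS_I): [ct.cell(GradeClass.EXTRA, GradeClass.CLASS_I), GradeClass.CLASS_I],
        (GradeClass.EXTRA, GradeClass.EXTRA): [4, GradeClass.CLASS_I],
        (GradeClass.CLASS_I, GradeClass.CLASS_II): [ct.cell(GradeClass.CLASS_I, GradeClass.CLASS_II), GradeClass.CLASS_II],
        (GradeClass.CLASS_I, GradeClass.EXTRA): [ct.cell(GradeClass.CLASS_I, GradeClass.EXTRA), GradeClass.EXTRA],
        (GradeClass.CLASS_I, GradeClass.CLASS_I): [2, GradeClass.EXTRA],
    }
    new_est = []
    for e, a in zip(est, act):
        move = moves.get((e, a))
        if move is not None and move[0] > 0:
            move[0] -= 1
            new_est.append(move[1])
        else:
            new_est.append(e)
    return build_confusion(new_est, act)
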