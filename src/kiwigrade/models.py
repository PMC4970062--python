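"""Linear estimation of hidden fruit dimensions.

A single top-view camera cannot see the minimum equatorial-section diameter
(MiDES) of a kiwifruit lying on its flat face, and volume cannot be measured
on a sorting line at all. Both are instead estimated from the measurable
parameters — weight W (g), length L (mm), MaDES (mm) and projected area PA
(cm^2) — through multiple linear regression models.

This module ships the published calibration models for 'Hayward' kiwifruit:

    MiDES_est [mm]  = -2.36 - 0.08 W - 3.71e-4 PA + 0.66 L + 0.24 MaDES
    V_est    [cm^3] = -2.69 + 0.93 W + 5.47e-5 PA + 0.09 L + 1.65e-3 MaDES

and a stepwise multiple linear regression (SMLR) fitter — forward entry and
backward removal on coefficient p-values — for recalibrating either model on
new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ModelError

__all__ = [
    "PREDICTOR_NAMES",
    "LinearModel",
    "FruitEstimate",
    "SmlrResult",
    "builtin_mides_model",
    "builtin_volume_model",
    "estimate",
    "compute_ratios",
    "fit_smlr",
]

#: Canonical predictor names, in published-table order.
PREDICTOR_NAMES = ("weight_g", "pa_cm2", "length_mm", "mades_mm")


@dataclass(frozen=True)
class LinearModel:
    """A named linear estimator: response = intercept + sum(coef * predictor)."""

    response: str
    intercept: float
    coefficients: Mapping[str, float]

    def predict(self, values: Mapping[str, float]) -> float:
        total = self.intercept
        for name, coef in self.coefficients.items():
            if name not in values:
                raise ModelError(f"missing predictor {name!r} for model {self.response!r}")
            total += coef * float(values[name])
        return total

    def to_json(self) -> str:
        return json.dumps(
            {
                "response": self.response,
                "intercept": self.intercept,
                "coefficients": dict(self.coefficients),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        obj = json.loads(text)
        return cls(
            response=obj["response"],
            intercept=float(obj["intercept"]),
            coefficients={k: float(v) for k, v in obj["coefficients"].items()},
        )


@dataclass(frozen=True)
class FruitEstimate:
    """Model outputs for one fruit: estimated hidden sizes and shape ratios.

    ``ratios`` holds the six descriptor ratios in the unit conventions of the
    reference study: weight/length (g/mm), weight/PA (g/cm^2), weight/MaDES
    (g/mm), length/MaDES (dimensionless), length/PA (mm/cm^2), and MaDES/PA
    (mm/cm^2). ``mmr`` = MiDES_est/MaDES and ``mlr`` = MaDES/length are the
    grading-relevant shape ratios.
    """

    mides_est_mm: float
    volume_est_cm3: float | None
    mmr: float
    mlr: float
    ratios: Mapping[str, float] = field(default_factory=dict)


def builtin_mides_model() -> LinearModel:
    """Published calibration model for the hidden minimum equatorial diameter."""
    return LinearModel(
        response="mides_mm",
        intercept=-2.36,
        coefficients={
            "weight_g": -0.08,
            "pa_cm2": -3.71e-4,
            "length_mm": 0.66,
            "mades_mm": 0.24,
        },
    )


def builtin_volume_model() -> LinearModel:
    """Published calibration model for fruit volume (cm^3)."""
    return LinearModel(
        response="volume_cm3",
        intercept=-2.69,
        coefficients={
            "weight_g": 0.93,
            "pa_cm2": 5.47e-5,
            "length_mm": 0.09,
            "mades_mm": 1.65e-3,
        },
    )


def estimate(measurement, model: LinearModel) -> float:
    """Evaluate a linear model on a fruit measurement.

    ``measurement`` may be a :class:`~kiwigrade.image.FruitMeasurement`
    (its ``as_predictors`` mapping is used), or any mapping from predictor
    name to value in model units (weight g, sizes mm, PA cm^2).
    """
    values = measurement.as_predictors() if hasattr(measurement, "as_predictors") else measurement
    return model.predict(values)


def compute_ratios(
    measurement,
    mides_est_mm: float,
    volume_est_cm3: float | None = None,
) -> FruitEstimate:
    """Derive the grading ratios and the six descriptor ratios for one fruit."""
    values = measurement.as_predictors() if hasattr(measurement, "as_predictors") else measurement
    w = float(values["weight_g"])
    length = float(values["length_mm"])
    mades = float(values["mades_mm"])
    pa = float(values["pa_cm2"])
    for name, v in (("weight_g", w), ("length_mm", length), ("mades_mm", mades), ("pa_cm2", pa)):
        if v <= 0:
            raise ModelError(f"{name} must be positive to form ratios, got {v}")
    return FruitEstimate(
        mides_est_mm=mides_est_mm,
        volume_est_cm3=volume_est_cm3,
        mmr=mides_est_mm / mades,
        mlr=mades / length,
        ratios={
            "weight_length": w / length,
            "weight_pa": w / pa,
            "weight_mades": w / mades,
            "length_mades": length / mades,
            "length_pa": length / pa,
            "mades_pa": mades / pa,
        },
    )


# ---------------------------------------------------------------------------
# stepwise multiple linear regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmlrResult:
    """Outcome of a stepwise fit: the selected predictors (entry order), the
    refit model, and the usual significance statistics."""

    selected: tuple[str, ...]
    model: LinearModel
    tvalues: Mapping[str, float]
    pvalues: Mapping[str, float]
    fvalue: float
    f_pvalue: float
    nobs: int

    def report(self) -> str:
        lines = [
            f"Stepwise linear regression for {self.model.response!r} "
            f"(n = {self.nobs})",
            f"{'Parameter':<12} {'Coefficient':>12} {'t':>9} {'p':>8}",
        ]
        for name in self.selected:
            lines.append(
                f"{name:<12} {self.model.coefficients[name]:>12.4g} "
                f"{self.tvalues[name]:>9.2f} {self.pvalues[name]:>8.3f}"
            )
        lines.append(f"{'Constant':<12} {self.model.intercept:>12.4g}")
        if math.isfinite(self.fvalue):
            lines.append(f"F = {self.fvalue:.2f}, p = {self.f_pvalue:.3g}")
        return "\n".join(lines)


def _ols(y: np.ndarray, x: np.ndarray):
    design = sm.add_constant(x, has_constant="add")
    return sm.OLS(y, design).fit()


def _design(data: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    return data.loc[:, list(names)].to_numpy(dtype=np.float64)


def _is_singular(data: pd.DataFrame, names: Sequence[str]) -> bool:
    x = sm.add_constant(_design(data, names), has_constant="add")
    return np.linalg.matrix_rank(x) < x.shape[1]


def fit_smlr(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> SmlrResult:
    """Stepwise multiple linear regression with forward entry / backward removal.

    At each forward step the candidate whose coefficient (when added to the
    current model) has the smallest p-value enters if that p-value is at most
    ``alpha_enter``; after every entry, included predictors whose p-value
    exceeds ``alpha_remove`` are dropped, worst first. Candidates whose
    addition makes the design matrix singular are skipped. The returned model
    is the ordinary least-squares refit on the final selection; residual
    degrees of freedom are n - k - 1.
    """
    if candidates is None:
        candidates = [c for c in PREDICTOR_NAMES if c in data.columns]
    candidates = list(candidates)
    if len(data) < 10:
        raise ModelError(f"need at least 10 rows to fit, got {len(data)}")
    if not candidates:
        raise ModelError("need at least one candidate predictor")
    if alpha_enter > alpha_remove:
        raise ModelError("alpha_enter must not exceed alpha_remove")
    missing = [c for c in candidates + [response] if c not in data.columns]
    if missing:
        raise ModelError(f"columns absent from data: {missing}")

    y = data[response].to_numpy(dtype=np.float64)
    selected: list[str] = []
    # a constant response has no variance to explain; p-values are undefined
    if np.ptp(y) == 0.0:
        return SmlrResult(
            selected=(),
            model=LinearModel(response=response, intercept=float(y[0]), coefficients={}),
            tvalues={},
            pvalues={},
            fvalue=float("nan"),
            f_pvalue=float("nan"),
            nobs=len(y),
        )
    while True:
        changed = False
        # forward entry
        best_name, best_p = None, np.inf
        for name in candidates:
            if name in selected:
                continue
            trial = selected + [name]
            if _is_singular(data, trial):
                continue
            fit = _ols(y, _design(data, trial))
            p = float(fit.pvalues[-1])
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p <= alpha_enter:
            selected.append(best_name)
            changed = True
        # backward removal
        while len(selected) > 0:
            fit = _ols(y, _design(data, selected))
            pvals = np.asarray(fit.pvalues[1:], dtype=np.float64)
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break

    fit = _ols(y, _design(data, selected)) if selected else _ols(y, np.empty((len(y), 0)))
    params = np.asarray(fit.params, dtype=np.float64)
    tvals = np.asarray(fit.tvalues, dtype=np.float64)
    pvals = np.asarray(fit.pvalues, dtype=np.float64)
    model = LinearModel(
        response=response,
        intercept=float(params[0]),
        coefficients={name: float(params[i + 1]) for i, name in enumerate(selected)},
    )
    return SmlrResult(
        selected=tuple(selected),
        model=model,
        tvalues={name: float(tvals[i + 1]) for i, name in enumerate(selected)},
        pvalues={name: float(pvals[i + 1]) for i, name in enumerate(selected)},
        fvalue=float(fit.fvalue) if selected else float("nan"),
        f_pvalue=float(fit.f_pvalue) if selected else float("nan"),
        nobs=int(fit.nobs),
    )
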