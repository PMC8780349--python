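"""Fit candidate maturation curves to child:adult ratio data and select the
final form by leave-one-out cross-validation (LOOCV).

Three candidate functional forms describe how a skin parameter's
child:adult ratio approaches 1 with postnatal age (days):

* sigmoid      ``a * Age / (b + Age) + c``
* hill         ``a * Age^n / (b^n + Age^n) + c``
* polynomial   ``a * Age^n + b * Age^m + c``

Fitting is unweighted nonlinear least squares on the ratio scale with
multi-start initialization (start boxes span the magnitudes of the
published coefficient sets; scale-like parameters are sampled
log-uniformly).  The form with the lowest mean squared leave-one-out
prediction error wins; ties go to the form with fewer parameters, then to
the lower residual sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .skin_physiology import MaturationModel, _evaluate_form

__all__ = [
    "RatioDataset",
    "FitResult",
    "FORM_PARAMS",
    "fit_form",
    "loocv",
    "select_model",
]

#: Parameter names per candidate form, in optimization order.
FORM_PARAMS: Dict[str, Tuple[str, ...]] = {
    "sigmoid": ("a", "b", "c"),
    "hill": ("a", "b", "c", "n"),
    "polynomial": ("a", "b", "c", "n", "m"),
}

# start/fit boxes per parameter: (low, high, log-uniform sampling?)
_BOXES: Dict[str, Tuple[float, float, bool]] = {
    "a": (-100.0, 100.0, False),
    "b": (-100.0, 100.0, False),
    "c": (0.0, 2.0, False),
    "n": (0.01, 8.0, True),
    "m": (-1.0, 8.0, False),
}
# sigmoid/hill b is an age scale in days, not a polynomial coefficient
_BOX_AGE_SCALE = (1.0, 1e4, True)


@dataclass(frozen=True)
class RatioDataset:
    """Child:adult ratio observations for one skin parameter."""

    parameter_id: str
    age_days: np.ndarray
    ratio: np.ndarray
    source_label: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        age = np.asarray(self.age_days, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "age_days", age)
        object.__setattr__(self, "ratio", ratio)
        if age.shape != ratio.shape or age.ndim != 1:
            raise ValueError("age_days and ratio must be matching 1-D arrays")
        if age.size < 4:
            raise ValueError("need at least 4 records")
        if np.any(age < 0):
            raise ValueError("ages must be >= 0")
        if np.any(ratio <= 0):
            raise ValueError("ratios must be > 0")

    @property
    def n(self) -> int:
        return int(self.age_days.size)

    def to_frame(self) -> pd.DataFrame:
        labels = self.source_label or ("",) * self.n
        return pd.DataFrame(
            {
                "parameter_id": self.parameter_id,
                "age_days": self.age_days,
                "ratio": self.ratio,
                "source_label": list(labels),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatioDataset":
        pid = frame["parameter_id"].iloc[0]
        return cls(
            parameter_id=str(pid),
            age_days=frame["age_days"].to_numpy(float),
            ratio=frame["ratio"].to_numpy(float),
            source_label=tuple(frame.get("source_label", pd.Series([""] * len(frame)))),
        )

    def drop(self, index: int) -> "RatioDataset":
        keep = np.arange(self.n) != index
        labels = self.source_label or ("",) * self.n
        return RatioDataset(
            self.parameter_id,
            self.age_days[keep],
            self.ratio[keep],
            tuple(np.asarray(labels, dtype=object)[keep]),
        )


@dataclass
class FitResult:
    """Best multi-start least-squares solution for one functional form."""

    form: str
    coefficients: Dict[str, float] = field(default_factory=dict)
    rss: float = np.inf
    converged: bool = False
    loocv_error: Optional[float] = None
    n_failed_folds: int = 0

    def predict(self, age_days) -> np.ndarray:
        return _evaluate_form(self.form, self.coefficients, np.asarray(age_days, float))


def _boxes_for(form: str) -> List[Tuple[float, float, bool]]:
    boxes = []
    for name in FORM_PARAMS[form]:
        if name == "b" and form in ("sigmoid", "hill"):
            boxes.append(_BOX_AGE_SCALE)
        else:
            boxes.append(_BOXES[name])
    return boxes


def _draw_start(rng: np.random.Generator, boxes) -> np.ndarray:
    values = []
    for low, high, log_uniform in boxes:
        if log_uniform and low > 0:
            values.append(np.exp(rng.uniform(np.log(low), np.log(high))))
        else:
            values.append(rng.uniform(low, high))
    return np.array(values)


def _residual_fn(form: str, data: RatioDataset):
    age, ratio = data.age_days, data.ratio

    def residuals(x: np.ndarray) -> np.ndarray:
        coeff = dict(zip(FORM_PARAMS[form], x))
        with np.errstate(all="ignore"):
            pred = _evaluate_form(form, coeff, age)
        pred = np.where(np.isfinite(pred), pred, 1e6)
        return pred - ratio

    return residuals


def fit_form(
    form: str, data: RatioDataset, starts: int = 20, seed: int = 0
) -> FitResult:
    """Multi-start nonlinear least squares of one candidate form."""
    if form not in FORM_PARAMS:
        raise ValueError(f"unknown form {form!r}")
    n_params = len(FORM_PARAMS[form])
    if data.n < n_params:
        raise ValueError(f"{form} needs at least {n_params} records, got {data.n}")

    boxes = _boxes_for(form)
    lower = np.array([b[0] for b in boxes])
    upper = np.array([b[1] for b in boxes])
    residuals = _residual_fn(form, data)
    rng = np.random.default_rng(seed)

    best: Optional[FitResult] = None
    for _ in range(starts):
        x0 = _draw_start(rng, boxes)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lower, upper), method="trf", max_nfev=400
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best.rss:
            best = FitResult(
                form=form,
                coefficients=dict(zip(FORM_PARAMS[form], map(float, sol.x))),
                rss=rss,
                converged=bool(sol.success or sol.status > 0),
            )
    if best is None:
        return FitResult(form=form, coefficients={}, rss=np.inf, converged=False)
    return best


def loocv(form: str, data: RatioDataset, starts: int = 20, seed: int = 0) -> float:
    """Mean squared leave-one-out prediction error for one form.

    Folds whose refit fails to converge are excluded (with a warning).
    """
    n_params = len(FORM_PARAMS[form])
    if data.n < n_params + 2:
        raise ValueError(
            f"LOOCV needs at least {n_params + 2} records for {form}, got {data.n}"
        )
    errors, failed = [], 0
    for i in range(data.n):
        sub = data.drop(i)
        fit = fit_form(form, sub, starts=starts, seed=seed + 1 + i)
        if not fit.converged:
            failed += 1
            continue
        pred = float(fit.predict(np.array([data.age_days[i]]))[0])
        errors.append((pred - data.ratio[i]) ** 2)
    if failed:
        warnings.warn(f"{failed} LOOCV fold(s) failed to converge for {form}")
    if not errors:
        raise RuntimeError(f"all LOOCV folds failed for {form}")
    return float(np.mean(errors))


def _cap_age_from_curve(fit: FitResult, max_age: float = 36500.0) -> Optional[float]:
    """Age at which the fitted curve first reaches ratio 1, if it does."""

    def f(age: float) -> float:
        return float(fit.predict(np.array([age]))[0]) - 1.0

    ages = np.linspace(0.0, max_age, 4000)
    values = fit.predict(ages) - 1.0
    sign_change = np.nonzero(np.diff(np.sign(values)) != 0)[0]
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    return float(brentq(f, ages[i], ages[i + 1]))


def select_model(
    data: RatioDataset,
    forms: Sequence[str] = ("sigmoid", "hill", "polynomial"),
    starts: int = 20,
    seed: int = 0,
) -> Tuple[FitResult, MaturationModel]:
    """LOOCV model selection; returns the winner and a capped ratio model.

    Ties (within floating noise) are broken by fewer parameters, then by
    lower residual sum of squares.
    """
    if len(forms) < 1:
        raise ValueError("need at least one candidate form")
    candidates: List[FitResult] = []
    for form in forms:
        fit = fit_form(form, data, starts=starts, seed=seed)
        if not fit.converged:
            continue
        fit.loocv_error = loocv(form, data, starts=starts, seed=seed)
        candidates.append(fit)
    if not candidates:
        raise RuntimeError("no candidate form converged")

    candidates.sort(
        key=lambda f: (round(f.loocv_error, 12), len(FORM_PARAMS[f.form]), f.rss)
    )
    winner = candidates[0]
    cap = _cap_age_from_curve(winner)
    model = MaturationModel(
        parameter_id=data.parameter_id,
        form=winner.form,  # type: ignore[arg-type]
        coefficients=dict(winner.coefficients),
        cap_age=cap,
    )
    return winner, model
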