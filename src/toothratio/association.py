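"""Correlation and simple linear regression between SATR and the Bolton ratio.

Both statistics are computed from closed forms on ratio *fractions*
(0.857, not 85.7%): the regression y = a + b*x relating the simplified
ratio x to the anterior Bolton ratio y is only dimensionally consistent on
fractions.  Percent inputs are detected and converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["LinearFit", "pearson_r", "ols_fit", "predict_abr", "as_fraction"]


def as_fraction(values: Sequence[float]) -> np.ndarray:
    """Coerce ratio values to fractions; percent-scale input (>2) is divided by 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size and np.median(np.abs(arr)) > 2.0:
        arr = arr / 100.0
    return arr


@dataclass(frozen=True)
class LinearFit:
    """OLS fit y = intercept + slope * x with its correlation and test."""

    intercept: float
    slope: float
    r: float
    p: float
    n: int

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x

    def __str__(self) -> str:
        return (
            f"y = {self.intercept:.3f} + {self.slope:.3f}x "
            f"(r = {self.r:.3f}, p = {self.p:.3g}, n = {self.n})"
        )


def _check_xy(xs, ys) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("correlation undefined: a variable has zero variance")
    return x, y


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value.

    p is from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x, y = _check_xy(xs, ys)
    n = len(x)
    dx = x - x.mean()
    dy = y - y.mean()
    r = float(dx @ dy / math.sqrt((dx @ dx) * (dy @ dy)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def ols_fit(xs: Sequence[float], ys: Sequence[float]) -> LinearFit:
    """Simple ordinary-least-squares fit from the normal-equation closed form.

    slope = cov(x, y)/var(x); intercept = mean(y) - slope*mean(x).
    Residuals sum to zero by construction.
    """
    x, y = _check_xy(xs, ys)
    r, p = pearson_r(x, y)
    dx = x - x.mean()
    dy = y - y.mean()
    slope = float(dx @ dy / (dx @ dx))
    intercept = float(y.mean() - slope * x.mean())
    return LinearFit(intercept=intercept, slope=slope, r=r, p=p, n=len(x))


def predict_abr(fit, satr_value: float) -> float:
    """Predicted anterior Bolton ratio (fraction) from a SATR fraction.

    ``fit`` may be a :class:`LinearFit` or an (intercept, slope) pair.
    """
    if not 0.0 < satr_value < 2.0:
        raise ValueError(
            f"SATR must be a fraction in (0, 2); got {satr_value} "
            "(did you pass a percent?)"
        )
    if isinstance(fit, LinearFit):
        intercept, slope = fit.intercept, fit.slope
    else:
        intercept, slope = fit
    return intercept + slope * satr_value
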