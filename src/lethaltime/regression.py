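"""The log-log lethal-time law: ln(LT50) = a + b * ln(C).

Ordinary least squares on natural-log-transformed concentration and median
lethal time. With b < 0 (the usual case) the law says lethality accelerates
as a power of concentration; it is the bridge from a handful of bioassay
concentrations to the arbitrary component concentrations that occur inside
a mixture.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy import stats

from .bioassay import LtcRegression
from .errors import DomainError, SingularDesignError


def fit_loglog(points: Iterable[tuple[float, float]]) -> LtcRegression:
    """Fit ln(LT50) = a + b*ln(C) by ordinary least squares.

    ``points`` are (concentration mg/L, LT50 hours) pairs; all must be
    positive. Median lethal times longer than the study window (probit
    extrapolations) are legitimate inputs and are fitted like any other
    point.
    """
    pts = [(float(c), float(lt)) for c, lt in points]
    if len(pts) < 2:
        raise DomainError("need at least 2 points")
    c = np.array([p[0] for p in pts])
    lt = np.array([p[1] for p in pts])
    if np.any(c <= 0) or np.any(lt <= 0):
        raise DomainError("concentrations and lethal times must be positive")
    if len(np.unique(c)) < 2:
        raise SingularDesignError("all concentrations identical; slope undefined")

    x = np.log(c)
    y = np.log(lt)
    res = stats.linregress(x, y)
    # r^2 of a 2-point (or perfectly collinear) fit is exactly 1
    r2 = 1.0 if len(pts) == 2 else float(res.rvalue**2)
    return LtcRegression(
        a=float(res.intercept),
        b=float(res.slope),
        r2=min(r2, 1.0),
        n=len(pts),
        c_range=(float(c.min()), float(c.max())),
    )


def predict_lt50(coeffs: LtcRegression, concentration: float) -> float:
    """Median lethal time exp(a + b*ln(C)) at an arbitrary concentration."""
    if concentration <= 0:
        raise DomainError("concentration must be positive")
    return float(np.exp(coeffs.a + coeffs.b * np.log(concentration)))


def is_extrapolation(coeffs: LtcRegression, concentration: float) -> bool:
    """True when ``concentration`` lies outside the fitted range.

    Extrapolation is the point of the law (mixture components sit at
    concentrations never tested singly), so this is a flag, not an error.
    """
    if coeffs.c_range is None:
        return False
    lo, hi = coeffs.c_range
    return not (lo <= concentration <= hi)
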