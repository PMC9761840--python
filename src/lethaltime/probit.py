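"""Maximum-likelihood probit analysis of quantal dose-response data.

The model is probit(p) = intercept + slope * log10(level), where *level* is
either a concentration (mg/L, giving LC50-type estimates) or an exposure
time (hours, giving LT50-type estimates). Fitting is classical
Fisher-scoring / IRLS, delegated to statsmodels' binomial GLM with a probit
link; groups with 0% or 100% response stay in the likelihood. Effective
levels (LCx / LTx) are back-transformed from the fitted line and their 95%
limits come from Fieller's theorem on the line's covariance, inflated by the
Pearson heterogeneity factor chi2/df when it exceeds 1 (in which case a
t critical value on df is used instead of the normal 1.96) — the convention
of Finney-style probit software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import ConvergenceError, DataValidationError, DomainError, SeparationError

Metameter = str  # "concentration" | "time"


@dataclass(frozen=True)
class ProbitFit:
    """A fitted probit line on a log10 metameter."""

    intercept: float
    slope: float
    metameter: Metameter
    chi2: float
    df: int
    cov: tuple[tuple[float, float], tuple[float, float]]
    n_groups: int
    level_range: tuple[float, float]
    converged: bool = True
    log_base: float = 10.0

    @property
    def heterogeneity(self) -> float:
        """Pearson chi2/df; > 1 signals extra-binomial scatter."""
        return self.chi2 / self.df if self.df > 0 else float("nan")

    def predicted_fraction(self, level: float) -> float:
        return float(stats.norm.cdf(self.intercept + self.slope * np.log10(level)))


@dataclass(frozen=True)
class EffectiveLevel:
    """A back-transformed effective level (e.g. LC50, LT50) with 95% limits."""

    p: float
    estimate: float
    lower95: float | None
    upper95: float | None
    extrapolated: bool = False
    limits_defined: bool = True


def _validate_groups(
    groups: Iterable[tuple[float, int, float]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = [(float(l), float(n), float(d)) for l, n, d in groups]
    if not g:
        raise DataValidationError("no groups supplied")
    levels = np.array([x[0] for x in g])
    n = np.array([x[1] for x in g])
    dead = np.array([x[2] for x in g])
    if np.any(levels <= 0):
        raise DataValidationError("all levels must be positive")
    if np.any(n <= 0):
        raise DataValidationError("all group sizes must be positive")
    if np.any(dead < 0) or np.any(dead > n):
        raise DataValidationError("deaths must lie in [0, n_exposed]")
    if len(np.unique(levels)) < 2:
        raise DataValidationError("need at least 2 distinct levels")
    return levels, n, dead


def _is_separated(levels: np.ndarray, n: np.ndarray, dead: np.ndarray) -> bool:
    """True when no finite MLE exists (all-or-nothing responses only,
    perfectly ordered, or a constant response of 0% / 100%)."""
    p = dead / n
    interior = (p > 0) & (p < 1)
    if np.any(interior):
        return False
    if np.all(p == 0) or np.all(p == 1):
        return True
    # only 0% and 100% groups: separated iff they do not interleave
    lo = levels[p == 1].min()
    hi = levels[p == 0].max()
    return bool(lo > hi)


def fit_probit(
    groups: Iterable[tuple[float, int, float]],
    metameter: Metameter = "concentration",
) -> ProbitFit:
    """Fit probit(p) = a + b*log10(level) by maximum likelihood.

    Parameters
    ----------
    groups
        Iterable of ``(level, n_exposed, n_dead)``. ``n_dead`` may be
        fractional when percentages are being treated as quantal responses
        of a nominal group.
    metameter
        ``"concentration"`` for LC-type fits, ``"time"`` for LT-type fits.

    Raises
    ------
    SeparationError
        When the data are completely separated and the MLE does not exist.
    ConvergenceError
        When IRLS fails to converge.
    """
    if metameter not in ("concentration", "time"):
        raise DomainError(f"unknown metameter {metameter!r}")
    levels, n, dead = _validate_groups(groups)
    if _is_separated(levels, n, dead):
        raise SeparationError(
            "complete separation: every group responded 0% or 100%; "
            "only an interval statement about the median is possible"
        )

    x = np.log10(levels)
    exog = sm.add_constant(x)
    endog = dead / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(
            endog,
            exog,
            family=sm.families.Binomial(link=sm.families.links.Probit()),
            var_weights=n,
        )
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # statsmodels raises PerfectSeparation etc.
            raise ConvergenceError(f"probit IRLS failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("probit IRLS produced non-finite parameters")

    intercept, slope = (float(v) for v in res.params)
    fitted = stats.norm.cdf(intercept + slope * x)
    fitted = np.clip(fitted, 1e-12, 1 - 1e-12)
    chi2 = float(np.sum((dead - n * fitted) ** 2 / (n * fitted * (1 - fitted))))
    df = max(len(levels) - 2, 0)
    cov = np.asarray(res.cov_params())
    return ProbitFit(
        intercept=intercept,
        slope=slope,
        metameter=metameter,
        chi2=chi2,
        df=df,
        cov=((float(cov[0, 0]), float(cov[0, 1])), (float(cov[1, 0]), float(cov[1, 1]))),
        n_groups=len(levels),
        level_range=(float(levels.min()), float(levels.max())),
        converged=bool(getattr(res, "converged", True)),
    )


def effective_level(fit: ProbitFit, p: float) -> EffectiveLevel:
    """Invert the fitted line at mortality fraction ``p`` with Fieller limits.

    The estimate is 10**((probit(p) - intercept)/slope). Extrapolation
    beyond the fitted level range is permitted and flagged. When Fieller's
    g >= 1 the limits do not exist and the estimate is returned with
    ``limits_defined=False``.
    """
    if not (0.0 < p < 1.0):
        raise DomainError("p must be a mortality fraction in (0, 1)")
    if fit.slope <= 0:
        raise DomainError(
            "fitted slope is not positive: response does not increase with level"
        )
    z = float(stats.norm.ppf(p))
    a, b = fit.intercept, fit.slope
    m = (z - a) / b
    estimate = 10.0 ** m
    extrapolated = not (fit.level_range[0] <= estimate <= fit.level_range[1])

    cov = np.asarray(fit.cov, dtype=float)
    het = fit.heterogeneity
    if fit.df > 0 and np.isfinite(het) and het > 1.0:
        cov = cov * het
        crit = float(stats.t.ppf(0.975, fit.df))
    else:
        crit = float(stats.norm.ppf(0.975))
    vaa, vab, vbb = cov[0, 0], cov[0, 1], cov[1, 1]

    # Fieller: roots in rho of (z - a - b*rho)^2 = crit^2 * Var(a + b*rho)
    c2 = crit * crit
    qa = b * b - c2 * vbb
    qb = -2.0 * (b * (z - a) + c2 * vab)
    qc = (z - a) ** 2 - c2 * vaa
    disc = qb * qb - 4.0 * qa * qc
    if qa <= 0 or disc < 0:
        return EffectiveLevel(
            p=p,
            estimate=estimate,
            lower95=None,
            upper95=None,
            extrapolated=extrapolated,
            limits_defined=False,
        )
    r = np.sqrt(disc)
    lo = (-qb - r) / (2.0 * qa)
    hi = (-qb + r) / (2.0 * qa)
    return EffectiveLevel(
        p=p,
        estimate=estimate,
        lower95=10.0 ** min(lo, hi),
        upper95=10.0 ** max(lo, hi),
        extrapolated=extrapolated,
    )


def lc_at_percents(
    fit: ProbitFit, percents: Sequence[float]
) -> list[EffectiveLevel]:
    """Effective levels for several mortality fractions (e.g. 0.05..0.90)."""
    return [effective_level(fit, p) for p in percents]
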