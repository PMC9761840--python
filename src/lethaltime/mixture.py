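"""Mixture lethality by lethal-time addition plus the hyperbolic model.

The core method:

1. split a total mixture concentration into component concentrations by
   the exact mixing-ratio weights,
2. obtain each component's median lethal time at its own concentration
   from the log-log law ln(LT50) = a + b*ln(C),
3. combine them with the lethal-time-addition rule

       LT50_mix = 1 / sum_i(C_i / LT_i)

   where C_i are the absolute component concentrations in mg/L, and
4. turn the mixture LT50 into time-resolved percentage mortality with the
   hyperbolic (Michaelis-Menten-shaped) model

       P(t) = P100 * t / (LT50 + t)

   which passes through 0 at t = 0, P100/2 at t = LT50 and saturates at
   P100.

A 96-h mixture LC50 is then recovered either by a probit fit of the
predicted mortalities against total concentration (the default, mirroring
how a bioassay would be analysed) or by root-solving LT50_mix(C) = t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .bioassay import MixturePrediction, MixtureSpec, LtcRegression
from .errors import DataValidationError, DomainError
from .probit import EffectiveLevel, ProbitFit, effective_level, fit_probit
from .regression import is_extrapolation, predict_lt50

DEFAULT_TIMES = (24.0, 48.0, 72.0, 96.0)


@dataclass(frozen=True)
class HyperbolicParams:
    """Parameters of the hyperbolic mortality curve."""

    lt50: float  # hours
    p100: float = 100.0  # ceiling, percent

    def __post_init__(self) -> None:
        if self.lt50 <= 0:
            raise DomainError("LT50 must be positive")
        if not (0.0 < self.p100 <= 100.0):
            raise DomainError("P100 must be in (0, 100]")


def component_concentrations(spec: MixtureSpec, total: float) -> tuple[float, ...]:
    """Split a total concentration by the exact ratio weights.

    C_i = total * r_i / sum(r); the split always sums back to the total.
    Rounded display values of published recipes are never used here.
    """
    if total <= 0:
        raise DomainError("total concentration must be positive")
    return tuple(total * p for p in spec.proportions)


def lethal_time_addition(pairs: Iterable[tuple[float, float]]) -> float:
    """Mixture LT50 = 1 / sum(C_i / LT_i) from (C_i mg/L, LT_i hours) pairs.

    C_i are absolute concentrations, so the result carries units of
    hours/(mg/L) * mg/L = hours only through the reciprocal-sum convention;
    it is bounded above by min_i(LT_i / C_i) and strictly decreases when a
    component is added.
    """
    pairs = [(float(c), float(lt)) for c, lt in pairs]
    if not pairs:
        raise DomainError("need at least one (C, LT) pair")
    for c, lt in pairs:
        if c <= 0:
            raise DomainError("component concentrations must be positive")
        if lt <= 0:
            raise DomainError("component lethal times must be positive")
    return 1.0 / sum(c / lt for c, lt in pairs)


def hyperbolic_mortality(params: HyperbolicParams, t: float) -> float:
    """Percentage mortality P100*t/(LT50 + t) at exposure time t (hours)."""
    if t < 0:
        raise DomainError("time must be >= 0")
    return params.p100 * t / (params.lt50 + t)


def predict_mixture_lt50_curve(
    spec: MixtureSpec,
    coeffs: Mapping[str, LtcRegression],
    totals: Sequence[float],
    times: Sequence[float] = DEFAULT_TIMES,
    p100: float = 100.0,
) -> list[MixturePrediction]:
    """Run the full chain for each total concentration.

    ``coeffs`` maps component name -> fitted log-log coefficients for the
    species at hand. Component concentrations are converted with each
    component's ``unit_scale`` before the log-log law is applied, so mixed
    mg/L / ug/L recipes stay on one scale.
    """
    missing = [n for n in spec.component_names if n not in coeffs]
    if missing:
        raise DataValidationError(f"no log-log coefficients for: {missing}")
    predictions = []
    for total in totals:
        concs = component_concentrations(spec, total)
        concs_mg = tuple(
            c * comp.unit_scale for c, comp in zip(concs, spec.components)
        )
        # on a mixed-unit recipe the mg/L masses do not sum to the nominal
        # total; the prediction carries the mg/L total
        total_mg = sum(concs_mg)
        lts = tuple(
            predict_lt50(coeffs[comp.name], c_mg)
            for c_mg, comp in zip(concs_mg, spec.components)
        )
        flags = tuple(
            is_extrapolation(coeffs[comp.name], c_mg)
            for c_mg, comp in zip(concs_mg, spec.components)
        )
        lt_mix = lethal_time_addition(zip(concs_mg, lts))
        params = HyperbolicParams(lt50=lt_mix, p100=p100)
        curve = tuple((float(t), hyperbolic_mortality(params, t)) for t in times)
        predictions.append(
            MixturePrediction(
                total_concentration=float(total_mg),
                component_names=spec.component_names,
                component_concentrations=concs_mg,
                component_lt50s=lts,
                lt50_mix=lt_mix,
                mortality_curve=curve,
                extrapolated=flags,
            )
        )
    return predictions


def mixture_lt50(
    spec: MixtureSpec, coeffs: Mapping[str, LtcRegression], total: float
) -> float:
    """LT50_mix at one total concentration (steps 1-3 only)."""
    return predict_mixture_lt50_curve(spec, coeffs, [total], times=())[0].lt50_mix


def hm_predicted_lc50(
    predictions: Sequence[MixturePrediction],
    t: float = 96.0,
    n_nominal: int = 10,
) -> EffectiveLevel:
    """Mixture LC50 at time ``t`` by probit on the predicted mortalities.

    The predicted percentage mortalities at ``t`` are treated as quantal
    responses of a nominal group of ``n_nominal`` organisms and fitted
    against log10 total concentration — the same analysis an observed
    bioassay would get.
    """
    groups = []
    interior = 0
    for pred in predictions:
        p = pred.mortality_at(t) / 100.0
        if 0.0 < p < 1.0:
            interior += 1
        groups.append((pred.total_concentration, n_nominal, n_nominal * p))
    if interior < 2:
        raise DataValidationError(
            "need >= 2 predictions with mortality strictly between 0 and 100%"
        )
    fit = fit_probit(groups, metameter="concentration")
    return effective_level(fit, 0.5)


def hm_probit_fit(
    predictions: Sequence[MixturePrediction], t: float = 96.0, n_nominal: int = 10
) -> ProbitFit:
    """The underlying probit fit used by :func:`hm_predicted_lc50`."""
    groups = [
        (p.total_concentration, n_nominal, n_nominal * p.mortality_at(t) / 100.0)
        for p in predictions
    ]
    return fit_probit(groups, metameter="concentration")


def hm_lc50_by_inversion(
    spec: MixtureSpec,
    coeffs: Mapping[str, LtcRegression],
    t: float = 96.0,
    c_bracket: tuple[float, float] | None = None,
    totals_hint: Sequence[float] | None = None,
) -> float:
    """Cross-check: the total concentration where LT50_mix(C) = t.

    Solved by Brent's method on log10 C. The default bracket spans
    [min(totals)/10, max(totals)*10] when ``totals_hint`` is given.
    """
    if c_bracket is None:
        if totals_hint is None:
            raise DomainError("supply either c_bracket or totals_hint")
        c_bracket = (min(totals_hint) / 10.0, max(totals_hint) * 10.0)

    def f(log_c: float) -> float:
        return np.log(mixture_lt50(spec, coeffs, 10.0 ** log_c)) - np.log(t)

    lo, hi = np.log10(c_bracket[0]), np.log10(c_bracket[1])
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise DomainError(
            f"LT50_mix(C) = {t} h has no root in [{c_bracket[0]}, {c_bracket[1]}] mg/L"
        )
    root = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(10.0 ** root)
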