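"""The concentration-addition (CA) reference model for mixtures.

At a common effect level x, component effect concentrations LCx_i combine
as a proportion-weighted harmonic mean:

    LCx_mix = 1 / sum_i(p_i / LCx_i)

with p_i the mixture proportions (summing to 1). The CA-predicted mixture
LC50 is then obtained by a probit fit of the effect levels against
log10(LCx_mix) over a grid of effect levels (default 5, 15, 35, 60, 90%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bioassay import MixtureSpec
from .errors import DataValidationError, DomainError
from .probit import EffectiveLevel, ProbitFit, effective_level, fit_probit, lc_at_percents

DEFAULT_EFFECT_LEVELS = (0.05, 0.15, 0.35, 0.60, 0.90)


@dataclass(frozen=True)
class CAEffectRow:
    """One effect level of a CA table."""

    x: float  # effect fraction
    component_lcx: tuple[float, ...]  # mg/L
    proportions: tuple[float, ...]
    lcx_mix: float  # mg/L

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise DataValidationError("proportions must sum to 1")
        if not (
            min(self.component_lcx) - 1e-12
            <= self.lcx_mix
            <= max(self.component_lcx) + 1e-12
        ):
            raise DataValidationError(
                "a harmonic mixture LCx must lie between the component extremes"
            )


def ca_lcx(component_lcx: Sequence[float], proportions: Sequence[float]) -> float:
    """LCx_mix = 1 / sum(p_i / LCx_i): proportion-weighted harmonic mean."""
    if len(component_lcx) != len(proportions):
        raise DataValidationError("component_lcx and proportions differ in length")
    if len(component_lcx) == 0:
        raise DataValidationError("need at least one component")
    lcx = np.asarray(component_lcx, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if np.any(lcx <= 0) or np.any(p <= 0):
        raise DomainError("effect concentrations and proportions must be positive")
    if abs(p.sum() - 1.0) > 1e-6:
        raise DataValidationError(f"proportions sum to {p.sum()}, not 1")
    return float(1.0 / np.sum(p / lcx))


def ca_rows_from_lcx(
    lcx_by_level: Mapping[float, Sequence[float]],
    proportions: Sequence[float],
) -> list[CAEffectRow]:
    """Build CA rows from tabulated component effect concentrations.

    ``lcx_by_level`` maps effect fraction -> component LCx values, in the
    same order as ``proportions``. This is the route used when the
    single-chemical effect concentrations come from a published table
    rather than from in-package probit fits.
    """
    rows = []
    for x in sorted(lcx_by_level):
        lcx = tuple(float(v) for v in lcx_by_level[x])
        rows.append(
            CAEffectRow(
                x=float(x),
                component_lcx=lcx,
                proportions=tuple(float(p) for p in proportions),
                lcx_mix=ca_lcx(lcx, proportions),
            )
        )
    return rows


def ca_table(
    fits: Sequence[ProbitFit],
    proportions: Sequence[float],
    percents: Sequence[float] = DEFAULT_EFFECT_LEVELS,
    spec: MixtureSpec | None = None,
    strict: bool = False,
) -> list[CAEffectRow]:
    """CA rows from per-component probit fits over an effect-level grid.

    With ``strict=True`` and a ``spec``, the proportions are recomputed
    from the spec's declared component order and a warning is emitted when
    they disagree with the supplied ``proportions`` (guards against
    transposed proportion/component pairings in hand-built tables).
    """
    if len(fits) != len(proportions):
        raise DataValidationError("one proportion per component fit required")
    props = tuple(float(p) for p in proportions)
    if strict and spec is not None:
        declared = spec.proportions
        if any(abs(d - p) > 1e-6 for d, p in zip(declared, props)):
            warnings.warn(
                f"proportions {props} disagree with the declared component "
                f"order of {spec.name!r} ({declared}); using the declared order",
                stacklevel=2,
            )
            props = declared
    per_component = [lc_at_percents(fit, percents) for fit in fits]
    rows = []
    for j, x in enumerate(percents):
        lcx = tuple(levels[j].estimate for levels in per_component)
        rows.append(
            CAEffectRow(
                x=float(x), component_lcx=lcx, proportions=props, lcx_mix=ca_lcx(lcx, props)
            )
        )
    return rows


def ca_predicted_lc50(
    rows: Sequence[CAEffectRow], n_nominal: int = 10
) -> EffectiveLevel:
    """CA-predicted mixture LC50: probit of x against log10(LCx_mix).

    The effect fractions are treated as quantal responses of a nominal
    group of ``n_nominal``, mirroring :func:`~lethaltime.mixture.hm_predicted_lc50`.
    """
    if len(rows) < 2 or len({r.x for r in rows}) < 2:
        raise DataValidationError("need >= 2 rows at distinct effect levels")
    groups = [(r.lcx_mix, n_nominal, n_nominal * r.x) for r in rows]
    fit = fit_probit(groups, metameter="concentration")
    return effective_level(fit, 0.5)
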