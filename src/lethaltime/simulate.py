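"""Synthetic time-to-death bioassays under the probit tolerance model.

The generator draws each organism's death time from a log-normal tolerance
law whose median at concentration C is the log-log prediction
exp(a + b*ln(C)) and whose spread on the log10-time axis is 1/slope, where
``slope`` is the probit slope per log10 hour. That is exactly the implicit
model of probit LT50 analysis, so the package's estimators are consistent
on this generator by construction. Deaths after the study window are
censored as survivors; cumulative counts are emitted on an hourly grid.

The default design mirrors a standard acute test: 10 fish per aquarium in
duplicate (20 per concentration pooled), hourly observation, 96-h window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bioassay import QuantalObservation
from .errors import DataValidationError, SeparationError
from .probit import effective_level, fit_probit
from .regression import fit_loglog


@dataclass(frozen=True)
class SimulationScenario:
    """Ground truth and design for one synthetic single-chemical bioassay."""

    name: str
    a: float  # log-log intercept, ln-hours
    b: float  # log-log slope
    probit_slope: float  # probit slope per log10 hour; spread = 1/slope
    concentrations: tuple[float, ...]  # mg/L
    n_per_group: int = 20  # 10 fish x 2 replicate aquaria, pooled
    study_end: float = 96.0  # hours
    observation_step: float = 1.0  # hourly counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probit_slope <= 0:
            raise DataValidationError("probit slope must be positive")
        if self.n_per_group <= 0:
            raise DataValidationError("n_per_group must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise DataValidationError("concentrations must be positive")
        if self.study_end <= 0 or self.observation_step <= 0:
            raise DataValidationError("study window and step must be positive")

    def true_lt50(self, concentration: float) -> float:
        return float(np.exp(self.a + self.b * np.log(concentration)))

    @property
    def observation_times(self) -> np.ndarray:
        n = int(round(self.study_end / self.observation_step))
        return np.arange(1, n + 1) * self.observation_step


def draw_death_times(
    scenario: SimulationScenario, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Uncensored death times (hours) for one concentration group."""
    median = scenario.true_lt50(concentration)
    log10_t = rng.normal(
        np.log10(median), 1.0 / scenario.probit_slope, scenario.n_per_group
    )
    return 10.0 ** log10_t


def simulate_time_to_death(
    scenario: SimulationScenario,
) -> dict[float, list[QuantalObservation]]:
    """Simulate the bioassay: per concentration, cumulative hourly counts.

    Returns concentration -> observations on the grid. Identical seeds give
    identical tables; one generator per scenario, no global state.
    """
    rng = np.random.default_rng(scenario.seed)
    times = scenario.observation_times
    out: dict[float, list[QuantalObservation]] = {}
    for conc in scenario.concentrations:
        deaths = draw_death_times(scenario, conc, rng)
        deaths = deaths[deaths <= scenario.study_end]  # censoring
        cum = np.searchsorted(np.sort(deaths), times, side="right")
        out[conc] = [
            QuantalObservation(
                concentration=conc,
                time=float(t),
                n_exposed=scenario.n_per_group,
                n_dead=int(c),
            )
            for t, c in zip(times, cum)
        ]
    return out


def estimate_lt50s(
    data: dict[float, list[QuantalObservation]]
) -> dict[float, float]:
    """Probit LT50 per concentration from cumulative time-mortality counts.

    Concentrations where no deaths occurred by study end carry no
    time-to-death information and are skipped, as are groups whose probit
    fit is degenerate (complete separation at the hourly resolution).
    """
    lt50s: dict[float, float] = {}
    for conc, obs_list in data.items():
        if not any(o.n_dead > 0 for o in obs_list):
            continue
        groups = [(o.time, o.n_exposed, o.n_dead) for o in obs_list if o.time > 0]
        try:
            fit = fit_probit(groups, metameter="time")
            lt50s[conc] = effective_level(fit, 0.5).estimate
        except SeparationError:
            continue
    return lt50s


@dataclass(frozen=True)
class RecoveryReport:
    """Truth vs estimate for one generator -> estimator round trip."""

    true_a: float
    true_b: float
    est_a: float
    est_b: float
    r2: float
    n_concentrations_used: int
    lt50_by_concentration: dict[float, float] = field(repr=False, default_factory=dict)

    @property
    def bias_a(self) -> float:
        return self.est_a - self.true_a

    @property
    def bias_b(self) -> float:
        return self.est_b - self.true_b


def recover_pipeline(scenario: SimulationScenario) -> RecoveryReport:
    """Simulate, estimate per-concentration LT50s, refit the log-log law.

    The full estimation chain the package applies to real data, run on data
    whose truth is known; reports recovered (a, b) and the fit's r2.
    """
    if len(scenario.concentrations) < 4:
        raise DataValidationError("recovery needs >= 4 concentrations")
    data = simulate_time_to_death(scenario)
    lt50s = estimate_lt50s(data)
    if len(lt50s) < 2:
        raise DataValidationError(
            "fewer than 2 concentrations yielded an LT50; increase n or levels"
        )
    fit = fit_loglog(sorted(lt50s.items()))
    return RecoveryReport(
        true_a=scenario.a,
        true_b=scenario.b,
        est_a=fit.a,
        est_b=fit.b,
        r2=fit.r2,
        n_concentrations_used=len(lt50s),
        lt50_by_concentration=lt50s,
    )
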