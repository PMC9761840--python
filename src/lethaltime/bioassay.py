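"""Core bioassay data structures and delimited-text I/O.

Conventions used throughout the package:

* concentrations are mg/L; a per-component ``unit_scale`` converts
  components quoted on another scale (e.g. micrograms per litre,
  ``unit_scale=1e-3``) onto mg/L before any arithmetic;
* times are hours;
* mortality counts are pooled over replicate aquaria, so one
  ``n_exposed`` per concentration group.

The CSV dialect is fixed: comma separator, dot decimal, UTF-8, header row
``chemical,species,concentration_mg_per_L,time_h,n_exposed,n_dead``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataValidationError, DomainError, SchemaError

BIOASSAY_COLUMNS = (
    "chemical",
    "species",
    "concentration_mg_per_L",
    "time_h",
    "n_exposed",
    "n_dead",
)


@dataclass(frozen=True)
class QuantalObservation:
    """Cumulative dead-out-of-exposed for one concentration group at one time."""

    concentration: float  # mg/L
    time: float  # hours since start of exposure
    n_exposed: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise DataValidationError(
                f"concentration must be positive, got {self.concentration}"
            )
        if self.time < 0:
            raise DataValidationError(f"time must be >= 0, got {self.time}")
        if self.n_exposed < 0 or self.n_dead < 0:
            raise DataValidationError("counts must be nonnegative")
        if self.n_dead > self.n_exposed:
            raise DataValidationError(
                f"n_dead ({self.n_dead}) exceeds n_exposed ({self.n_exposed})"
            )

    @property
    def mortality_fraction(self) -> float:
        if self.n_exposed == 0:
            raise DomainError("mortality undefined for n_exposed = 0")
        return self.n_dead / self.n_exposed


def mortality_percent(obs: QuantalObservation) -> float:
    """Observed percentage mortality, 100 * n_dead / n_exposed."""
    return 100.0 * obs.mortality_fraction


@dataclass(frozen=True)
class Component:
    """One chemical in a mixture: a name, a ratio weight and a unit scale.

    ``ratio`` is a relative weight (the mixing ratio column of a recipe,
    e.g. 33.95 : 1); ``unit_scale`` multiplies concentrations quoted for
    this component onto mg/L (1e-3 for a component quoted in ug/L).
    """

    name: str
    ratio: float
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise DataValidationError(f"ratio weight must be > 0 for {self.name!r}")
        if self.unit_scale <= 0:
            raise DataValidationError(f"unit scale must be > 0 for {self.name!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """An ordered mixture recipe for one species.

    Proportions are always derived from the exact ratio weights, never from
    rounded display values. A single-component "mixture" is accepted so the
    degenerate forms of the mixture operations stay testable.
    """

    components: tuple[Component, ...]
    species: str = ""
    name: str = ""
    stock_concentration: float | None = None  # g/L, metadata only

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise DataValidationError("a mixture needs at least one component")

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def proportions(self) -> tuple[float, ...]:
        total = sum(c.ratio for c in self.components)
        return tuple(c.ratio / total for c in self.components)


def make_mixture(
    name: str,
    components: Sequence[tuple[str, float]] | Mapping[str, float],
    species: str = "",
    unit_scales: Mapping[str, float] | None = None,
    stock_concentration: float | None = None,
) -> MixtureSpec:
    """Convenience constructor from (name, ratio) pairs or a mapping."""
    items = components.items() if isinstance(components, Mapping) else components
    scales = unit_scales or {}
    comps = tuple(
        Component(n, r, scales.get(n, 1.0)) for n, r in items
    )
    return MixtureSpec(
        components=comps,
        species=species,
        name=name,
        stock_concentration=stock_concentration,
    )


@dataclass(frozen=True)
class LtcRegression:
    """Coefficients of the log-log lethal-time law ln(LT50) = a + b*ln(C).

    ``a`` is on the natural-log hours scale, ``b`` is dimensionless (usually
    negative: higher concentration kills faster). ``c_range`` records the
    fitted concentration range so predictions outside it can be flagged as
    extrapolation.
    """

    a: float
    b: float
    r2: float
    n: int
    c_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataValidationError("a log-log fit needs n >= 2 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise DataValidationError(f"r2 outside [0, 1]: {self.r2}")


@dataclass(frozen=True)
class MixturePrediction:
    """Everything computed for one total mixture concentration."""

    total_concentration: float  # mg/L
    component_names: tuple[str, ...]
    component_concentrations: tuple[float, ...]  # mg/L
    component_lt50s: tuple[float, ...]  # hours
    lt50_mix: float  # hours
    mortality_curve: tuple[tuple[float, float], ...]  # (t hours, P percent)
    extrapolated: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if abs(sum(self.component_concentrations) - self.total_concentration) > 1e-9 * max(
            1.0, self.total_concentration
        ):
            raise DataValidationError(
                "component concentrations do not sum to the total"
            )
        if self.lt50_mix <= 0:
            raise DataValidationError("mixture LT50 must be positive")

    def mortality_at(self, t: float) -> float:
        for ti, p in self.mortality_curve:
            if ti == t:
                return p
        raise KeyError(f"time {t} not on the prediction grid")


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_bioassay_table(
    path: str | Path,
) -> dict[tuple[str, str], list[QuantalObservation]]:
    """Read a CSV bioassay table, grouped by (chemical, species).

    Within each group, records are sorted by concentration then time, and
    cumulative mortality must be nondecreasing in time within each
    concentration.
    """
    df = pd.read_csv(path)
    missing = [c for c in BIOASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    groups: dict[tuple[str, str], list[QuantalObservation]] = {}
    for idx, row in df.iterrows():
        try:
            obs = QuantalObservation(
                concentration=float(row["concentration_mg_per_L"]),
                time=float(row["time_h"]),
                n_exposed=int(row["n_exposed"]),
                n_dead=int(row["n_dead"]),
            )
        except DataValidationError as exc:
            raise DataValidationError(f"row {idx}: {exc}") from exc
        key = (str(row["chemical"]), str(row["species"]))
        groups.setdefault(key, []).append(obs)

    for key, obs_list in groups.items():
        obs_list.sort(key=lambda o: (o.concentration, o.time))
        by_conc: dict[float, int] = {}
        for o in obs_list:
            prev = by_conc.get(o.concentration)
            if prev is not None and o.n_dead < prev:
                raise DataValidationError(
                    f"group {key}, concentration {o.concentration}: cumulative "
                    "deaths decrease over time"
                )
            by_conc[o.concentration] = o.n_dead
    return groups


def write_bioassay_table(
    groups: Mapping[tuple[str, str], Iterable[QuantalObservation]],
    path: str | Path,
) -> None:
    """Inverse of :func:`read_bioassay_table` (field-for-field round trip)."""
    rows = []
    for (chemical, species), obs_list in groups.items():
        for o in obs_list:
            rows.append(
                {
                    "chemical": chemical,
                    "species": species,
                    "concentration_mg_per_L": o.concentration,
                    "time_h": o.time,
                    "n_exposed": o.n_exposed,
                    "n_dead": o.n_dead,
                }
            )
    pd.DataFrame(rows, columns=list(BIOASSAY_COLUMNS)).to_csv(path, index=False)
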