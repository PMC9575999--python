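"""Typed observation records for the three field-data streams.

* ``CowRecord`` — a radio-collared adult cow: tooth-estimated entry age,
  dated re-sighting events with locations along the migratory axis, and a
  terminal fate (interval-censored death, right-censoring at collar loss or
  study end, or exclusion as a suspected poaching mortality).
* ``HerdCountRecord`` — a dated herd-composition count: numbers of calves
  and cows classified (yearlings and bulls excluded from both counts).
* ``CalfDetectionRecord`` — per collared cow and calf-year, the dated binary
  sequence of whether a calf was detected with the cow.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from . import seasons

__all__ = [
    "Sighting",
    "CowRecord",
    "HerdCountRecord",
    "CalfObservation",
    "CalfDetectionRecord",
    "ReproductionParams",
    "ObservationSet",
]


@dataclass(frozen=True)
class Sighting:
    date: _dt.date
    location_km: float


@dataclass
class CowRecord:
    """Event history for one collared cow.

    ``events`` are the dated live re-sightings (strictly increasing dates,
    first at the entry date).  A death is interval-censored between the last
    live sighting and ``found_dead_date``; a record with no
    ``found_dead_date`` is right-censored at its last sighting.
    Suspected poaching mortalities are flagged and dropped from all
    vital-rate analyses.
    """

    cow_id: str
    entry_date: _dt.date
    entry_age: float  # yr, tooth-based point estimate
    events: list[Sighting]
    found_dead_date: Optional[_dt.date] = None
    poaching_suspect: bool = False

    def __post_init__(self) -> None:
        if self.entry_age <= 0:
            raise ValueError(f"{self.cow_id}: entry age must be > 0")
        if not self.events:
            raise ValueError(f"{self.cow_id}: needs at least one live event")
        dates = [e.date for e in self.events]
        if any(d1 <= d0 for d0, d1 in zip(dates, dates[1:])):
            raise ValueError(f"{self.cow_id}: event dates must be strictly increasing")
        if dates[0] != self.entry_date:
            raise ValueError(f"{self.cow_id}: first event must be at entry date")
        if self.found_dead_date is not None and self.found_dead_date < dates[-1]:
            raise ValueError(f"{self.cow_id}: found-dead date precedes last live sighting")

    @property
    def died(self) -> bool:
        return self.found_dead_date is not None

    @property
    def last_alive_date(self) -> _dt.date:
        return self.events[-1].date

    def age_at(self, date) -> float:
        return self.entry_age + seasons.years_between(self.entry_date, date)

    def location_at(self, date) -> float:
        """Piecewise-linear interpolation of recorded sighting locations
        (constant extrapolation beyond the first/last sighting)."""
        d = seasons.as_date(date)
        evs = self.events
        if d <= evs[0].date:
            return evs[0].location_km
        for e0, e1 in zip(evs, evs[1:]):
            if d <= e1.date:
                span = (e1.date - e0.date).days
                if span == 0:
                    return e1.location_km
                w = (d - e0.date).days / span
                return (1 - w) * e0.location_km + w * e1.location_km
        return evs[-1].location_km


@dataclass(frozen=True)
class HerdCountRecord:
    date: _dt.date
    location_km: float
    n_calves: int
    n_cows: int

    def __post_init__(self) -> None:
        if self.n_calves < 0 or self.n_cows < 0:
            raise ValueError("herd counts must be >= 0")

    @property
    def calf_year(self) -> int:
        return seasons.calf_year_of(self.date)

    @property
    def time_since_pulse(self) -> float:
        return seasons.years_between(
            seasons.birth_pulse_date(self.calf_year), self.date)


@dataclass(frozen=True)
class CalfObservation:
    date: _dt.date
    detected: bool


@dataclass
class CalfDetectionRecord:
    """Dated binary calf-detection sequence for one cow in one calf-year."""

    cow_id: str
    calf_year: int
    observations: list[CalfObservation]

    def __post_init__(self) -> None:
        pulse = seasons.birth_pulse_date(self.calf_year)
        nxt = seasons.birth_pulse_date(self.calf_year + 1)
        dates = [o.date for o in self.observations]
        if any(d1 <= d0 for d0, d1 in zip(dates, dates[1:])):
            raise ValueError(
                f"{self.cow_id}/{self.calf_year}: observation dates must be strictly increasing")
        for d in dates:
            if d < pulse or d >= nxt:
                raise ValueError(
                    f"{self.cow_id}/{self.calf_year}: observation {d} outside calf-year")


@dataclass(frozen=True)
class ReproductionParams:
    """Fecundity and calf-detection error rates.

    f : probability an adult cow produces a calf at the birth pulse; either
        a single value or a mapping calf-year -> value
    p : probability of correctly detecting a cow's calf when present
    q : probability of falsely detecting another cow's calf when absent
    """

    f: Union[float, Mapping[int, float]]
    p: float = 0.89
    q: float = 0.02

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("q", self.q)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for v in self._f_values():
            if not 0.0 < v < 1.0:
                raise ValueError(f"fecundity must be in (0,1), got {v}")

    def _f_values(self):
        return (self.f.values() if isinstance(self.f, Mapping) else (self.f,))

    def fecundity(self, calf_year: int) -> float:
        if isinstance(self.f, Mapping):
            return self.f[calf_year]
        return self.f


@dataclass
class ObservationSet:
    """The three validated record tables plus the validation log."""

    cows: list[CowRecord]
    herd_counts: list[HerdCountRecord]
    calf_obs: list[CalfDetectionRecord]
    validation_log: dict[str, int] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        ys: set[int] = set()
        for c in self.cows:
            ys.update(range(c.entry_date.year, c.last_alive_date.year + 1))
        for h in self.herd_counts:
            ys.add(h.date.year)
        return sorted(ys)

    @property
    def calf_years(self) -> list[int]:
        return sorted({h.calf_year for h in self.herd_counts}
                      | {c.calf_year for c in self.calf_obs})
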