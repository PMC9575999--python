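"""Study calendar: seasons, the birth pulse, and the migratory location axis.

The study system has a sharply seasonal climate — an extensive wet season
from December through May and a dry season from June through November — and
a strongly pulsed calving season peaking around 1 October.  Location along
the migratory corridor is reduced to a single signed distance (km) from a
reference point beyond the southeastern end of the range: the population
winters (wet season) in the southeast at low distances and spends the dry
season in the northwest at high distances, with transits in May–June
(northward) and October–November (southward).

All ages are continuous decimal years; date arithmetic assumes a
365.25-day year.
"""

from __future__ import annotations

import datetime as _dt
from typing import Union

DateLike = Union[_dt.date, _dt.datetime, str]

DAYS_PER_YEAR = 365.25

#: Months belonging to the wet season (December through May).
WET_MONTHS = frozenset({12, 1, 2, 3, 4, 5})

#: Month/day of the annual birth pulse.
BIRTH_PULSE = (10, 1)

#: Calving-season window during which herd counts are excluded
#: (presence of a calf with a cow cannot be reliably determined).
CALVING_WINDOW = ((9, 1), (10, 31))

#: Piecewise-constant monthly location (km along the migratory axis) of the
#: canonical seasonal movement cycle: southeast residency Dec–Apr, northward
#: transit May–June, northwest residency Jul–Oct, southward transit Nov.
MONTHLY_LOCATION_KM = {
    1: 20.0, 2: 20.0, 3: 20.0, 4: 20.0,
    5: 60.0, 6: 100.0,
    7: 120.0, 8: 120.0, 9: 120.0, 10: 120.0,
    11: 70.0, 12: 20.0,
}


def as_date(d: DateLike) -> _dt.date:
    """Coerce an ISO-8601 string / datetime / date to a ``datetime.date``."""
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))


def season_of(d: DateLike) -> str:
    """Return ``"wet"`` (Dec–May) or ``"dry"`` (Jun–Nov) for a date."""
    return "wet" if as_date(d).month in WET_MONTHS else "dry"


def is_wet(d: DateLike) -> bool:
    return as_date(d).month in WET_MONTHS


def in_calving_window(d: DateLike) -> bool:
    """True for dates inside the 1 Sep – 31 Oct herd-count exclusion window."""
    d = as_date(d)
    (m0, d0), (m1, d1) = CALVING_WINDOW
    return (d.month, d.day) >= (m0, d0) and (d.month, d.day) <= (m1, d1)


def birth_pulse_date(calf_year: int) -> _dt.date:
    """Date of the 1 October birth pulse opening calf-year ``calf_year``."""
    return _dt.date(calf_year, *BIRTH_PULSE)


def calf_year_of(d: DateLike) -> int:
    """Calf-year (year of the most recent birth pulse on or before ``d``)."""
    d = as_date(d)
    return d.year if (d.month, d.day) >= BIRTH_PULSE else d.year - 1


def years_between(d0: DateLike, d1: DateLike) -> float:
    """Signed elapsed time from ``d0`` to ``d1`` in decimal years."""
    return (as_date(d1) - as_date(d0)).days / DAYS_PER_YEAR


def add_years(d: DateLike, years: float) -> _dt.date:
    return as_date(d) + _dt.timedelta(days=round(years * DAYS_PER_YEAR))


def migratory_location(d: DateLike) -> float:
    """Location (km along the migratory axis) of the canonical herd movement
    cycle on a given date, at calendar-month resolution."""
    return MONTHLY_LOCATION_KM[as_date(d).month]


def month_boundaries(d0: _dt.date, d1: _dt.date) -> list[_dt.date]:
    """Dates splitting [d0, d1] at calendar-month boundaries.

    Returns a sorted list starting with ``d0`` and ending with ``d1``.  Each
    successive pair lies within a single calendar month (hence a single
    season, location value, and calendar year).
    """
    if d1 < d0:
        raise ValueError(f"interval reversed: {d0} > {d1}")
    out = [d0]
    cur = d0
    while True:
        nxt = (_dt.date(cur.year + 1, 1, 1) if cur.month == 12
               else _dt.date(cur.year, cur.month + 1, 1))
        if nxt >= d1:
            break
        out.append(nxt)
        cur = nxt
    out.append(d1)
    return out
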