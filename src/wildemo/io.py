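"""Delimited-text readers and writers for the three observation tables.

Formats (CSV, UTF-8, ISO-8601 dates):

* ``cows.csv`` — one row per cow event: cow_id, entry_date, entry_age_yr,
  event_date, location_km, status.  ``status`` is ``alive`` for live
  re-sightings, ``found_dead`` for the terminal carcass-discovery row of a
  death, and ``poaching_suspect`` for the terminal row of a suspected
  poaching mortality; a cow whose last row is ``alive`` is right-censored.
* ``herd_counts.csv`` — date, location_km, n_calves, n_cows.
* ``calf_obs.csv`` — cow_id, calf_year, date, detected (0/1).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from . import seasons
from .records import (CalfDetectionRecord, CalfObservation, CowRecord,
                      HerdCountRecord, Sighting)

__all__ = [
    "read_cows", "write_cows",
    "read_herd_counts", "write_herd_counts",
    "read_calf_obs", "write_calf_obs",
]

COW_COLUMNS = ["cow_id", "entry_date", "entry_age_yr", "event_date",
               "location_km", "status"]
HERD_COLUMNS = ["date", "location_km", "n_calves", "n_cows"]
CALF_COLUMNS = ["cow_id", "calf_year", "date", "detected"]


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")


def _parse_date(s, path, row) -> _dt.date:
    try:
        return seasons.as_date(str(s))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed date {s!r} in row {row}") from exc


def write_cows(cows: Sequence[CowRecord], path: Union[str, Path]) -> None:
    rows = []
    for c in cows:
        for e in c.events:
            rows.append((c.cow_id, c.entry_date.isoformat(), c.entry_age,
                         e.date.isoformat(), e.location_km, "alive"))
        if c.found_dead_date is not None:
            status = "poaching_suspect" if c.poaching_suspect else "found_dead"
            rows.append((c.cow_id, c.entry_date.isoformat(), c.entry_age,
                         c.found_dead_date.isoformat(),
                         c.events[-1].location_km, status))
    pd.DataFrame(rows, columns=COW_COLUMNS).to_csv(path, index=False)


def read_cows(path: Union[str, Path]) -> list[CowRecord]:
    df = pd.read_csv(path, dtype={"cow_id": str})
    _check_columns(df, COW_COLUMNS, path)
    out: list[CowRecord] = []
    for cow_id, grp in df.groupby("cow_id", sort=True):
        grp = grp.reset_index(drop=True)
        entry_date = _parse_date(grp.loc[0, "entry_date"], path, 0)
        entry_age = float(grp.loc[0, "entry_age_yr"])
        events = []
        found_dead = None
        poaching = False
        for i, row in grp.iterrows():
            d = _parse_date(row["event_date"], path, i)
            status = str(row["status"])
            if status == "alive":
                events.append(Sighting(d, float(row["location_km"])))
            elif status in ("found_dead", "poaching_suspect"):
                found_dead = d
                poaching = status == "poaching_suspect"
            else:
                raise ValueError(f"{path}: unknown status {status!r} "
                                 f"for cow {cow_id}")
        events.sort(key=lambda e: e.date)
        out.append(CowRecord(cow_id=str(cow_id), entry_date=entry_date,
                             entry_age=entry_age, events=events,
                             found_dead_date=found_dead,
                             poaching_suspect=poaching))
    return out


def write_herd_counts(counts: Sequence[HerdCountRecord],
                      path: Union[str, Path]) -> None:
    pd.DataFrame(
        [(h.date.isoformat(), h.location_km, h.n_calves, h.n_cows)
         for h in counts],
        columns=HERD_COLUMNS).to_csv(path, index=False)


def read_herd_counts(path: Union[str, Path]) -> list[HerdCountRecord]:
    df = pd.read_csv(path)
    _check_columns(df, HERD_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        n_calves, n_cows = int(row["n_calves"]), int(row["n_cows"])
        if n_calves < 0 or n_cows < 0:
            raise ValueError(f"{path}: negative count in row {i}")
        out.append(HerdCountRecord(
            date=_parse_date(row["date"], path, i),
            location_km=float(row["location_km"]),
            n_calves=n_calves, n_cows=n_cows))
    return out


def write_calf_obs(records: Sequence[CalfDetectionRecord],
                   path: Union[str, Path]) -> None:
    rows = [(r.cow_id, r.calf_year, o.date.isoformat(), int(o.detected))
            for r in records for o in r.observations]
    pd.DataFrame(rows, columns=CALF_COLUMNS).to_csv(path, index=False)


def read_calf_obs(path: Union[str, Path]) -> list[CalfDetectionRecord]:
    df = pd.read_csv(path, dtype={"cow_id": str})
    _check_columns(df, CALF_COLUMNS, path)
    out = []
    if df.empty:
        return out
    for (cow_id, cy), grp in df.groupby(["cow_id", "calf_year"], sort=True):
        obs = sorted(
            (CalfObservation(_parse_date(row["date"], path, i),
                             bool(int(row["detected"])))
             for i, row in grp.iterrows()),
            key=lambda o: o.date)
        out.append(CalfDetectionRecord(str(cow_id), int(cy), obs))
    return out
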