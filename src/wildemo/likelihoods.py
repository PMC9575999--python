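"""Likelihoods for the three observation streams.

* ``cc_loglik`` — collared-cow survival: left-truncated at the
  tooth-estimated entry age (each cow's history conditions on survival to
  entry) and interval-censored between the last live sighting and the
  found-dead date.
* ``hc_loglik`` — herd-composition counts: the expected calf fraction among
  classified calves+cows is r/(1+r) with r = f * S_c(t), the per-cow
  expected number of surviving calves at the count date.
* ``cd_loglik`` — calf-detection sequences: a hidden-state forward
  recursion over {no-calf-born, calf-present, calf-dead, calf-dissociated}
  with detection error (p for a present calf, q otherwise).  Because the
  three calf-absent states share one emission distribution, the forward sum
  collapses to a single pass over possible departure intervals, which is
  what the vectorized implementation computes.

Covariate paths are piecewise constant at calendar-month resolution: within
a month the season, calendar year, and location are fixed (cow locations
are interpolated from the record's own sightings; calf paths follow the
canonical migratory cycle).  Each stream has a ``compile_*`` function
producing flat numpy arrays so that repeated likelihood evaluations inside
the sampler cost a handful of vectorized operations.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np
from scipy.special import gammaln

from . import seasons
from .records import (CalfDetectionRecord, CowRecord, HerdCountRecord,
                      ReproductionParams)
from .siler import HazardModifiers, SilerParams, siler_cumulative_hazard, siler_hazard

__all__ = [
    "cc_loglik",
    "hc_loglik",
    "cd_loglik",
    "hc_expected_calf_fraction",
    "dissociation_probability",
    "first_year_survivorship",
    "calf_survivorship",
    "compile_cow_data",
    "compile_herd_data",
    "compile_calf_data",
    "CompiledCowData",
    "CompiledHerdData",
    "CompiledCalfData",
]

DISSOCIATION_ONSET = 0.75  # yr; calves begin dissociating from mothers


# ---------------------------------------------------------------------------
# covariate-path segmentation

def _segments(d0: _dt.date, d1: _dt.date, age_at_d0: float,
              location_fn: Callable[[_dt.date], float]):
    """Split [d0, d1] at month boundaries -> (a0, a1, wet, loc, year) tuples."""
    out = []
    bounds = seasons.month_boundaries(d0, d1)
    for lo, hi in zip(bounds, bounds[1:]):
        if hi <= lo:
            continue
        mid = lo + (hi - lo) / 2
        out.append((
            age_at_d0 + seasons.years_between(d0, lo),
            age_at_d0 + seasons.years_between(d0, hi),
            1.0 if lo.month in seasons.WET_MONTHS else 0.0,
            float(location_fn(mid)),
            lo.year,
        ))
    return out


class _SegmentArrays:
    """Flat per-segment arrays plus owning-record indices."""

    def __init__(self, segs, rec_idx, year_to_code, n_rec):
        self.a0 = np.array([s[0] for s in segs], dtype=float)
        self.a1 = np.array([s[1] for s in segs], dtype=float)
        self.wet = np.array([s[2] for s in segs], dtype=float)
        self.loc = np.array([s[3] for s in segs], dtype=float)
        self.year_code = np.array([year_to_code[s[4]] for s in segs], dtype=np.intp)
        self.rec = np.array(rec_idx, dtype=np.intp)
        self.n_rec = n_rec

    def __len__(self):
        return self.a0.size

    def modifier(self, mods: HazardModifiers, by: np.ndarray) -> np.ndarray:
        return np.exp(mods.beta_s * self.wet + mods.beta_l * self.loc
                      + by[self.year_code])

    def delta_H(self, params: SilerParams) -> np.ndarray:
        return (siler_cumulative_hazard(params, self.a1)
                - siler_cumulative_hazard(params, self.a0))


def _year_effect_vector(mods: HazardModifiers, year_levels: Sequence[int]) -> np.ndarray:
    return np.array([mods.year_effect(int(y)) for y in year_levels], dtype=float)


# ---------------------------------------------------------------------------
# collared-cow survival (CC)

@dataclass
class CompiledCowData:
    year_levels: np.ndarray
    surv: _SegmentArrays            # entry -> last-alive, all cows
    death: _SegmentArrays           # interval-censored death windows
    n_deaths: int
    exact_age: np.ndarray           # exact-time deaths (window < 1 day)
    exact_wet: np.ndarray
    exact_loc: np.ndarray
    exact_year_code: np.ndarray
    n_cows: int


def compile_cow_data(cows: Sequence[CowRecord]) -> CompiledCowData:
    """Precompute covariate-path segments for repeated CC evaluations.

    Poaching-suspect records must already have been removed (they are
    rejected here to fail fast).
    """
    years: set[int] = set()
    for c in cows:
        if c.poaching_suspect:
            raise ValueError(f"{c.cow_id}: poaching-suspect record in CC data; "
                             "drop these upstream")
        years.update(range(c.entry_date.year,
                           (c.found_dead_date or c.last_alive_date).year + 1))
    year_levels = np.array(sorted(years), dtype=int)
    y2c = {int(y): i for i, y in enumerate(year_levels)}

    s_segs, s_rec = [], []
    d_segs, d_rec = [], []
    ex_age, ex_wet, ex_loc, ex_yc = [], [], [], []
    n_deaths = 0
    for i, c in enumerate(cows):
        s = _segments(c.entry_date, c.last_alive_date, c.entry_age, c.location_at)
        s_segs.extend(s)
        s_rec.extend([i] * len(s))
        if c.died:
            window = (c.found_dead_date - c.last_alive_date).days
            if window < 0:
                raise ValueError(f"{c.cow_id}: negative death interval")
            if window == 0:  # exact-time death: hazard density
                a = c.age_at(c.found_dead_date)
                ex_age.append(a)
                ex_wet.append(1.0 if c.found_dead_date.month in seasons.WET_MONTHS else 0.0)
                ex_loc.append(c.location_at(c.found_dead_date))
                ex_yc.append(y2c[c.found_dead_date.year])
            else:
                d = _segments(c.last_alive_date, c.found_dead_date,
                              c.age_at(c.last_alive_date), c.location_at)
                d_segs.extend(d)
                d_rec.extend([n_deaths] * len(d))
                n_deaths += 1
    return CompiledCowData(
        year_levels=year_levels,
        surv=_SegmentArrays(s_segs, s_rec, y2c, len(cows)),
        death=_SegmentArrays(d_segs, d_rec, y2c, n_deaths),
        n_deaths=n_deaths,
        exact_age=np.array(ex_age, dtype=float),
        exact_wet=np.array(ex_wet, dtype=float),
        exact_loc=np.array(ex_loc, dtype=float),
        exact_year_code=np.array(ex_yc, dtype=np.intp),
        n_cows=len(cows),
    )


def cc_loglik(data: Union[Sequence[CowRecord], CompiledCowData],
              params: SilerParams, mods: HazardModifiers = HazardModifiers()) -> float:
    """Log-likelihood of the collared-cow survival data.

    Each cow contributes minus the cumulative modified hazard from entry age
    to last-alive age (left truncation: the history conditions on survival
    to entry), plus log(1 - exp(-dH)) across the death window for deaths,
    or nothing further for right-censored records.
    """
    cd = data if isinstance(data, CompiledCowData) else compile_cow_data(list(data))
    by = _year_effect_vector(mods, cd.year_levels)

    ll = -float(np.sum(cd.surv.modifier(mods, by) * cd.surv.delta_H(params)))
    if cd.n_deaths:
        w = cd.death.modifier(mods, by) * cd.death.delta_H(params)
        dH = np.bincount(cd.death.rec, weights=w, minlength=cd.n_deaths)
        if np.any(dH <= 0):
            return -np.inf
        ll += float(np.sum(np.log(-np.expm1(-dH))))
    if cd.exact_age.size:
        h = siler_hazard(params, cd.exact_age) * np.exp(
            mods.beta_s * cd.exact_wet + mods.beta_l * cd.exact_loc
            + by[cd.exact_year_code])
        if np.any(h <= 0):
            return -np.inf
        ll += float(np.sum(np.log(h)))
    return ll


# ---------------------------------------------------------------------------
# calf survivorship along the canonical migratory path

def _calf_segments(calf_year: int, t_end: float,
                   location_fn: Callable[[_dt.date], float]):
    pulse = seasons.birth_pulse_date(calf_year)
    end = seasons.add_years(pulse, t_end)
    segs = _segments(pulse, end, 0.0, location_fn)
    # pin the final boundary to exactly t_end (dates round to whole days)
    out = []
    for (a0, a1, wet, loc, yr) in segs:
        a1 = min(a1, t_end)
        if a1 > a0:
            out.append((a0, a1, wet, loc, yr))
    if out:
        last = out[-1]
        out[-1] = (last[0], t_end, last[2], last[3], last[4])
    return out


def calf_survivorship(params: SilerParams, mods: HazardModifiers,
                      calf_year: int, t: float,
                      location_fn: Callable[[_dt.date], float] = seasons.migratory_location,
                      ) -> float:
    """Survivorship of a calf from the 1 Oct pulse of ``calf_year`` to age
    ``t`` (yr) under the modified hazard along the migratory path."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 1.0
    H = 0.0
    for a0, a1, wet, loc, year in _calf_segments(calf_year, t, location_fn):
        mult = math.exp(mods.beta_s * wet + mods.beta_l * loc
                        + mods.year_effect(year))
        H += mult * (siler_cumulative_hazard(params, a1)
                     - siler_cumulative_hazard(params, a0))
    return math.exp(-H)


def first_year_survivorship(params: SilerParams,
                            mods: HazardModifiers = HazardModifiers(),
                            calf_year: int = 2015,
                            location_fn: Callable[[_dt.date], float] = seasons.migratory_location,
                            ) -> float:
    """First-year survivorship S1: birth pulse to age 1.0 along the
    canonical migratory path (reference year effects unless provided)."""
    return calf_survivorship(params, mods, calf_year, 1.0, location_fn)


def hc_expected_calf_fraction(f: float, params: SilerParams, mods: HazardModifiers,
                              time_since_pulse: float, calf_year: int,
                              location_fn: Callable[[_dt.date], float] = seasons.migratory_location,
                              ) -> float:
    """Expected fraction of calves among classified calves+cows at a herd
    count ``time_since_pulse`` years after the birth pulse.

    With per-cow expected surviving calves r = f * S_c(t), the calf:cow
    ratio is r and the calf fraction is r / (1 + r).
    """
    if time_since_pulse <= 0:
        raise ValueError("count must postdate the birth pulse "
                         "(counts near calving are excluded upstream)")
    r = f * calf_survivorship(params, mods, calf_year, time_since_pulse, location_fn)
    return r / (1.0 + r)


# ---------------------------------------------------------------------------
# herd-composition counts (HC)

@dataclass
class CompiledHerdData:
    calf_year_levels: np.ndarray
    segs: _SegmentArrays
    n_calves: np.ndarray
    n_total: np.ndarray
    rec_calf_year_code: np.ndarray
    log_binom_coef: np.ndarray
    n_records: int


def compile_herd_data(counts: Sequence[HerdCountRecord],
                      location_fn: Callable[[_dt.date], float] = seasons.migratory_location,
                      ) -> CompiledHerdData:
    kept = []
    skipped = 0
    for h in counts:
        if h.n_calves + h.n_cows == 0:
            skipped += 1
            continue
        if h.time_since_pulse <= 0:
            raise ValueError(f"herd count on {h.date} precedes its birth pulse")
        kept.append(h)
    if skipped:
        warnings.warn(f"skipped {skipped} herd count(s) with zero classified animals")

    cy_levels = np.array(sorted({h.calf_year for h in kept}), dtype=int)
    years = sorted({b[4] for h in kept
                    for b in _calf_segments(h.calf_year, h.time_since_pulse, location_fn)})
    y2c = {int(y): i for i, y in enumerate(years)}
    segs, rec = [], []
    for i, h in enumerate(kept):
        s = _calf_segments(h.calf_year, h.time_since_pulse, location_fn)
        segs.extend(s)
        rec.extend([i] * len(s))
    k = np.array([h.n_calves for h in kept], dtype=float)
    n = np.array([h.n_calves + h.n_cows for h in kept], dtype=float)
    cy2c = {int(y): i for i, y in enumerate(cy_levels)}
    sa = _SegmentArrays(segs, rec, y2c, len(kept))
    sa.year_levels = np.array(years, dtype=int)  # hazard-year levels
    return CompiledHerdData(
        calf_year_levels=cy_levels,
        segs=sa,
        n_calves=k,
        n_total=n,
        rec_calf_year_code=np.array([cy2c[h.calf_year] for h in kept], dtype=np.intp),
        log_binom_coef=gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1),
        n_records=len(kept),
    )


def hc_loglik(data: Union[Sequence[HerdCountRecord], CompiledHerdData],
              repro: ReproductionParams, params: SilerParams,
              mods: HazardModifiers = HazardModifiers()) -> float:
    """Binomial log-likelihood of calf counts among classified animals."""
    hd = data if isinstance(data, CompiledHerdData) else compile_herd_data(list(data))
    by = _year_effect_vector(mods, hd.segs.year_levels)
    w = hd.segs.modifier(mods, by) * hd.segs.delta_H(params)
    H = np.bincount(hd.segs.rec, weights=w, minlength=hd.n_records)
    f = np.array([repro.fecundity(int(y)) for y in hd.calf_year_levels])[
        hd.rec_calf_year_code]
    r = f * np.exp(-H)
    frac = r / (1.0 + r)
    ll = hd.log_binom_coef + hd.n_calves * np.log(frac) \
        + (hd.n_total - hd.n_calves) * np.log1p(-frac)
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# calf dissociation

def dissociation_probability(gamma_d: float, age) -> Union[float, np.ndarray]:
    """Probability a surviving calf is still associated with its mother.

    The dissociation hazard is max(0, gamma_d * (age - 0.75)), zero before
    0.75 yr, so the association survival is exp(-gamma_d*(age-0.75)^2 / 2)
    thereafter.
    """
    if gamma_d < 0:
        raise ValueError("gamma_d must be >= 0")
    age = np.asarray(age, dtype=float)
    excess = np.clip(age - DISSOCIATION_ONSET, 0.0, None)
    out = np.exp(-gamma_d * excess ** 2 / 2.0)
    return out if out.ndim else float(out)


def _dissociation_cumhaz(gamma_d: float, age: np.ndarray) -> np.ndarray:
    excess = np.clip(age - DISSOCIATION_ONSET, 0.0, None)
    return gamma_d * excess ** 2 / 2.0


# ---------------------------------------------------------------------------
# calf-detection sequences (CD)

@dataclass
class CompiledCalfData:
    calf_year_levels: np.ndarray
    segs: _SegmentArrays            # pulse -> last obs, split at months & obs times
    obs_end_ptr: np.ndarray         # (n_rec, K) index into prefix-sum of segments
    rec_start_ptr: np.ndarray       # (n_rec,)
    obs_age: np.ndarray             # (n_rec, K) padded
    obs_det: np.ndarray             # (n_rec, K) 0/1, padded 0
    obs_valid: np.ndarray           # (n_rec, K) bool
    rec_calf_year_code: np.ndarray
    n_records: int


def compile_calf_data(records: Sequence[CalfDetectionRecord],
                      location_fn: Callable[[_dt.date], float] = seasons.migratory_location,
                      ) -> CompiledCalfData:
    recs = [r for r in records if r.observations]
    cy_levels = np.array(sorted({r.calf_year for r in recs}), dtype=int)
    cy2c = {int(y): i for i, y in enumerate(cy_levels)}

    all_segs, seg_rec = [], []
    years: set[int] = set()
    per_rec_obs = []
    for r in recs:
        pulse = seasons.birth_pulse_date(r.calf_year)
        obs_dates = [o.date for o in r.observations]
        # split at month boundaries AND observation dates
        cuts = sorted(set(seasons.month_boundaries(pulse, obs_dates[-1]))
                      | set(obs_dates) | {pulse})
        segs = []
        for lo, hi in zip(cuts, cuts[1:]):
            if hi <= lo:
                continue
            mid = lo + (hi - lo) / 2
            segs.append((seasons.years_between(pulse, lo),
                         seasons.years_between(pulse, hi),
                         1.0 if lo.month in seasons.WET_MONTHS else 0.0,
                         float(location_fn(mid)), lo.year))
            years.add(lo.year)
        # pointer: for obs k, index of last segment ending at/before obs date
        ends = [s[1] for s in segs]
        ptrs = []
        for d in obs_dates:
            t = seasons.years_between(pulse, d)
            j = int(np.searchsorted(np.array(ends), t - 1e-12, side="left"))
            ptrs.append(min(j, len(segs) - 1) if segs else -1)
        per_rec_obs.append((segs, ptrs,
                            [seasons.years_between(pulse, d) for d in obs_dates],
                            [1.0 if o.detected else 0.0 for o in r.observations]))

    y2c = {int(y): i for i, y in enumerate(sorted(years))} if years else {}
    K = max((len(p[2]) for p in per_rec_obs), default=0)
    n_rec = len(recs)
    obs_end = np.zeros((n_rec, K), dtype=np.intp)
    obs_age = np.zeros((n_rec, K), dtype=float)
    obs_det = np.zeros((n_rec, K), dtype=float)
    valid = np.zeros((n_rec, K), dtype=bool)
    rec_start = np.zeros(n_rec, dtype=np.intp)
    offset = 0
    for i, (segs, ptrs, ages, dets) in enumerate(per_rec_obs):
        rec_start[i] = offset
        all_segs.extend(segs)
        seg_rec.extend([i] * len(segs))
        k = len(ages)
        obs_end[i, :k] = offset + np.asarray(ptrs) + 1  # prefix-sum index (1-based)
        obs_age[i, :k] = ages
        obs_det[i, :k] = dets
        valid[i, :k] = True
        offset += len(segs)
    sa = _SegmentArrays(all_segs, seg_rec, y2c, n_rec)
    sa.year_levels = np.array(sorted(years), dtype=int)
    return CompiledCalfData(
        calf_year_levels=cy_levels, segs=sa,
        obs_end_ptr=obs_end, rec_start_ptr=rec_start,
        obs_age=obs_age, obs_det=obs_det, obs_valid=valid,
        rec_calf_year_code=np.array([cy2c[r.calf_year] for r in recs], dtype=np.intp),
        n_records=n_rec,
    )


def cd_loglik(data: Union[Sequence[CalfDetectionRecord], CompiledCalfData],
              repro: ReproductionParams, params: SilerParams,
              mods: HazardModifiers = HazardModifiers()) -> float:
    """Hidden-state forward log-likelihood of the calf-detection sequences.

    Per cow-year the initial mass is f on calf-present (at the birth pulse)
    and 1-f on no-calf-born.  Between observations, calf-present mass decays
    through the modified calf-death hazard plus the dissociation hazard.
    Emissions: a detection has probability p while the calf is present and
    q in every calf-absent state (never born, dead, or dissociated); since
    those states share emissions, the forward sum reduces to a sum over the
    interval in which the calf departed.
    """
    cd = data if isinstance(data, CompiledCalfData) else compile_calf_data(list(data))
    if cd.n_records == 0:
        return 0.0
    by = _year_effect_vector(mods, cd.segs.year_levels)
    w = cd.segs.modifier(mods, by) * cd.segs.delta_H(params)
    csum = np.concatenate([[0.0], np.cumsum(w)])
    Hmod = csum[cd.obs_end_ptr] - csum[cd.rec_start_ptr][:, None]
    Lam = Hmod + _dissociation_cumhaz(mods.gamma_d, cd.obs_age)
    # padded positions carry arbitrary values; exp(-inf) = 0 masks them
    G = np.exp(-np.where(cd.obs_valid, Lam, np.inf))

    p, q = repro.p, repro.q
    det, vld = cd.obs_det, cd.obs_valid
    e_p = np.where(vld, np.where(det > 0, p, 1.0 - p), 1.0)
    e_q = np.where(vld, np.where(det > 0, q, 1.0 - q), 1.0)

    n, K = G.shape
    ones = np.ones((n, 1))
    Ge = np.concatenate([ones, G, np.zeros((n, 1))], axis=1)        # (n, K+2)
    wdep = Ge[:, :-1] - Ge[:, 1:]                                   # (n, K+1)
    PP = np.concatenate([ones, np.cumprod(e_p, axis=1)], axis=1)    # (n, K+1)
    SQ = np.concatenate([np.cumprod(e_q[:, ::-1], axis=1)[:, ::-1], ones],
                        axis=1)                                     # (n, K+1)
    L_present = np.sum(wdep * PP * SQ, axis=1)
    L_nocalf = SQ[:, 0]
    f = np.array([repro.fecundity(int(y)) for y in cd.calf_year_levels])[
        cd.rec_calf_year_code]
    L = (1.0 - f) * L_nocalf + f * L_present
    if np.any(L <= 0):
        return -np.inf
    return float(np.sum(np.log(L)))
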