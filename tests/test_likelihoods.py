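"""Likelihood functions for the three observation streams."""

import datetime as dt
from itertools import product

import numpy as np
import pytest

from wildemo import seasons
from wildemo.likelihoods import (DISSOCIATION_ONSET, _calf_segments,
                                 _dissociation_cumhaz, calf_survivorship,
                                 cc_loglik, cd_loglik, compile_calf_data,
                                 dissociation_probability,
                                 first_year_survivorship,
                                 hc_expected_calf_fraction, hc_loglik)
from wildemo.records import (CalfDetectionRecord, CalfObservation, CowRecord,
                             HerdCountRecord, ReproductionParams, Sighting)
from wildemo.siler import (HazardModifiers, SilerParams,
                           siler_cumulative_hazard)

CONST = lambda h: SilerParams(0, 1, h, 0, 1)  # noqa: E731
NOMODS = HazardModifiers()


def _cow(entry, entry_age, alive_days, found_dead_days=None, cow_id="C1",
         loc=50.0):
    events = [Sighting(entry + dt.timedelta(days=d), loc) for d in alive_days]
    fd = (entry + dt.timedelta(days=found_dead_days)
          if found_dead_days is not None else None)
    return CowRecord(cow_id=cow_id, entry_date=entry, entry_age=entry_age,
                     events=events, found_dead_date=fd)


class TestCowSurvivalLoglik:
    def test_censored_exponential(self):
        # one cow, constant hazard 0.1/yr, censored 2 yr after entry
        entry = dt.date(2014, 1, 15)
        cow = _cow(entry, 4.0, [0, int(round(2 * 365.25))])
        ll = cc_loglik([cow], CONST(0.1), NOMODS)
        dt_yr = seasons.years_between(entry, cow.last_alive_date)
        assert ll == pytest.approx(-0.1 * dt_yr, rel=1e-12)
        assert ll == pytest.approx(-0.2, abs=2e-4)

    def test_interval_censored_death_formula(self):
        # survival 1 yr from entry at age 5, then death inside a short window
        h = 0.5
        entry = dt.date(2014, 1, 15)
        cow = _cow(entry, 5.0, [0, 365], found_dead_days=380)
        ll = cc_loglik([cow], CONST(h), NOMODS)
        t_alive = 365 / 365.25
        t_win = 15 / 365.25
        want = -h * t_alive + np.log(1 - np.exp(-h * t_win))
        assert ll == pytest.approx(want, rel=1e-10)

    def test_interval_death_monte_carlo(self):
        # oracle: frequency of deaths in the window among exponential
        # lifetimes that survive the observation span
        h = 0.5
        entry = dt.date(2014, 1, 15)
        cow = _cow(entry, 5.0, [0, 365], found_dead_days=380)
        ll = cc_loglik([cow], CONST(h), NOMODS)
        rng = np.random.default_rng(42)
        n = 1_000_000
        t = rng.exponential(1 / h, size=n)
        p_hat = np.mean((t > 365 / 365.25) & (t <= 380 / 365.25))
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        assert np.exp(ll) == pytest.approx(p_hat, abs=4 * se)

    def test_doubling_hazard_shifts_by_cumhaz(self):
        # log-linearity of the survival term for a censored record
        entry = dt.date(2013, 3, 1)
        cow = _cow(entry, 3.0, [0, 200, 500])
        ll1 = cc_loglik([cow], CONST(0.2), NOMODS)
        ll2 = cc_loglik([cow], CONST(0.4), NOMODS)
        t = seasons.years_between(entry, cow.last_alive_date)
        assert ll1 - ll2 == pytest.approx(0.2 * t, rel=1e-10)

    def test_exact_time_death_uses_hazard_density(self):
        entry = dt.date(2014, 1, 15)
        cow = _cow(entry, 5.0, [0, 365], found_dead_days=365)
        ll = cc_loglik([cow], CONST(0.5), NOMODS)
        t_alive = 365 / 365.25
        assert ll == pytest.approx(-0.5 * t_alive + np.log(0.5), rel=1e-10)

    def test_left_truncation_excludes_pre_entry_hazard(self):
        # entry age enters only through the (age-dependent) hazard shape:
        # under senescent hazard an older entrant has lower survival odds
        p = SilerParams(0, 1, 0.02, 0.01, 0.4)
        young = _cow(dt.date(2014, 1, 15), 3.0, [0, 365])
        old = _cow(dt.date(2014, 1, 15), 12.0, [0, 365])
        assert cc_loglik([young], p) > cc_loglik([old], p)

    def test_poaching_suspect_rejected(self):
        cow = _cow(dt.date(2014, 1, 15), 5.0, [0, 100])
        cow.poaching_suspect = True
        with pytest.raises(ValueError):
            cc_loglik([cow], CONST(0.1))

    def test_season_modifier_splits_path(self):
        # a record spanning wet and dry months integrates each month under
        # its own modifier
        mods = HazardModifiers(beta_s=np.log(2.0))
        entry = dt.date(2014, 5, 20)  # wet May, then dry Jun-Nov
        cow = _cow(entry, 4.0, [0, 100])
        ll = cc_loglik([cow], CONST(0.3), mods)
        wet_days = (dt.date(2014, 6, 1) - entry).days
        dry_days = 100 - wet_days
        want = -0.3 * (2.0 * wet_days + dry_days) / 365.25
        assert ll == pytest.approx(want, rel=1e-10)


class TestHerdCountModel:
    def test_fraction_arithmetic(self):
        # r = f * S_c; fraction = r/(1+r): 0.68 x 0.56 -> 0.2758
        f, sc = 0.68, 0.56
        r = f * sc
        assert r / (1 + r) == pytest.approx(0.2758, abs=2e-4)

    def test_fraction_from_model(self):
        # zero-hazard calves: fraction = f/(1+f) at any t
        f = 0.68
        got = hc_expected_calf_fraction(f, CONST(0.0), NOMODS, 0.5, 2015)
        assert got == pytest.approx(f / (1 + f), rel=1e-12)

    def test_fraction_vanishes_with_fecundity(self):
        got = hc_expected_calf_fraction(1e-9, CONST(0.2), NOMODS, 0.5, 2015)
        assert got < 1e-8

    def test_fraction_monotonicity(self):
        lo = hc_expected_calf_fraction(0.4, CONST(0.3), NOMODS, 0.5, 2015)
        hi = hc_expected_calf_fraction(0.8, CONST(0.3), NOMODS, 0.5, 2015)
        assert hi > lo
        light = hc_expected_calf_fraction(0.6, CONST(0.1), NOMODS, 0.5, 2015)
        heavy = hc_expected_calf_fraction(0.6, CONST(0.9), NOMODS, 0.5, 2015)
        assert light > heavy

    def test_fraction_monte_carlo(self):
        # oracle: individual-based simulation of cows with Bernoulli(f)
        # calves thinned by survivorship to the count date
        f, t, cy = 0.68, 0.6, 2015
        params = SilerParams(1.2, 3.0, 0.1, 0.0, 1.0)
        mods = HazardModifiers(beta_s=0.25)
        sc = calf_survivorship(params, mods, cy, t)
        rng = np.random.default_rng(3)
        n = 1_000_000
        calves = rng.uniform(size=n) < f
        alive = calves & (rng.uniform(size=n) < sc)
        frac_hat = alive.sum() / (alive.sum() + n)
        got = hc_expected_calf_fraction(f, params, mods, t, cy)
        se = np.sqrt(frac_hat * (1 - frac_hat) / n)
        assert got == pytest.approx(frac_hat, abs=4 * se)

    def test_count_at_pulse_rejected(self):
        with pytest.raises(ValueError):
            hc_expected_calf_fraction(0.5, CONST(0.1), NOMODS, 0.0, 2015)

    def test_binomial_corner(self):
        # 0 calves / 50 cows at fraction phi -> 50 * ln(1 - phi)
        rec = HerdCountRecord(dt.date(2016, 1, 10), 20.0, 0, 50)
        repro = ReproductionParams(f=0.68)
        params = CONST(0.0)
        phi = hc_expected_calf_fraction(
            0.68, params, NOMODS, rec.time_since_pulse, rec.calf_year)
        ll = hc_loglik([rec], repro, params, NOMODS)
        assert ll == pytest.approx(50 * np.log(1 - phi), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        recs = [HerdCountRecord(dt.date(2016, 1, 5) + dt.timedelta(days=3 * i),
                                20.0, int(rng.integers(0, 20)),
                                int(rng.integers(20, 60)))
                for i in range(10)]
        repro = ReproductionParams(f=0.6)
        params = SilerParams(1.5, 3.0, 0.08, 0.01, 0.3)
        ll1 = hc_loglik(recs, repro, params, NOMODS)
        ll2 = hc_loglik(list(reversed(recs)), repro, params, NOMODS)
        assert ll1 == pytest.approx(ll2, rel=1e-13)

    def test_zero_classified_skipped_with_warning(self):
        recs = [HerdCountRecord(dt.date(2016, 1, 10), 20.0, 0, 0),
                HerdCountRecord(dt.date(2016, 1, 12), 20.0, 5, 45)]
        with pytest.warns(UserWarning, match="zero classified"):
            ll = hc_loglik(recs, ReproductionParams(f=0.6), CONST(0.1), NOMODS)
        assert np.isfinite(ll)


class TestDissociation:
    def test_before_onset(self):
        assert dissociation_probability(12.0, 0.5) == 1.0

    def test_zero_slope(self):
        for a in (0.2, 0.8, 1.0):
            assert dissociation_probability(0.0, a) == 1.0

    def test_closed_form_and_quadrature(self):
        got = dissociation_probability(8.0, 1.0)
        assert got == pytest.approx(np.exp(-0.25), rel=1e-12)
        from scipy.integrate import quad
        H, _ = quad(lambda u: max(0.0, 8.0 * (u - DISSOCIATION_ONSET)), 0, 1.0,
                    points=[DISSOCIATION_ONSET], epsrel=1e-12)
        assert got == pytest.approx(np.exp(-H), rel=1e-9)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            dissociation_probability(-1.0, 0.5)


def _cd_record(calf_year, day_offsets, detections, cow_id="C1"):
    pulse = seasons.birth_pulse_date(calf_year)
    obs = [CalfObservation(pulse + dt.timedelta(days=int(d)), bool(x))
           for d, x in zip(day_offsets, detections)]
    return CalfDetectionRecord(cow_id, calf_year, obs)


def _enumeration_loglik(rec, repro, params, mods):
    """Oracle: exhaustive enumeration over hidden-state paths on the
    observation grid with explicit 4x4 interval transition matrices."""
    pulse = seasons.birth_pulse_date(rec.calf_year)
    ts = [seasons.years_between(pulse, o.date) for o in rec.observations]
    dets = [o.detected for o in rec.observations]

    def cum_death(t):
        H = 0.0
        for a0, a1, wet, loc, yr in _calf_segments(
                rec.calf_year, t, seasons.migratory_location):
            m = np.exp(mods.beta_s * wet + mods.beta_l * loc
                       + mods.year_effect(yr))
            H += m * (siler_cumulative_hazard(params, a1)
                      - siler_cumulative_hazard(params, a0))
        return H

    def trans(t0, t1):
        dHc = cum_death(t1) - cum_death(t0)
        dD = float(_dissociation_cumhaz(mods.gamma_d, np.array(t1))
                   - _dissociation_cumhaz(mods.gamma_d, np.array(t0)))
        stay = np.exp(-dHc - dD)
        leave = 1.0 - stay
        tot = dHc + dD
        to_dead = leave * (dHc / tot) if tot > 0 else 0.0
        T = np.zeros((4, 4))  # states: none, present, dead, dissociated
        T[0, 0] = T[2, 2] = T[3, 3] = 1.0
        T[1, 1], T[1, 2], T[1, 3] = stay, to_dead, leave - to_dead
        return T

    n = len(ts)
    Ts = [trans(0.0 if k == 0 else ts[k - 1], ts[k]) for k in range(n)]

    def emit(state, det):
        pr = repro.p if state == 1 else repro.q
        return pr if det else 1 - pr

    total = 0.0
    for s0 in (0, 1):
        p0 = repro.fecundity(rec.calf_year) if s0 == 1 else \
            1 - repro.fecundity(rec.calf_year)
        for path in product(range(4), repeat=n):
            pr = p0
            prev = s0
            for k in range(n):
                pr *= Ts[k][prev, path[k]] * emit(path[k], dets[k])
                if pr == 0.0:
                    break
                prev = path[k]
            total += pr
    return float(np.log(total))


class TestCalfDetectionLoglik:
    PARAMS = SilerParams(1.5, 3.0, 0.1, 0.01, 0.3)
    MODS = HazardModifiers(beta_s=0.3, beta_l=-0.002,
                           beta_y={2015: 0.1, 2016: -0.1}, gamma_d=6.0)
    REPRO = ReproductionParams(f=0.7, p=0.85, q=0.05)

    def test_perfect_detection_immortal_calves(self):
        # p=1 unreachable by validation; p ~ 1 gives loglik ~ ln(f)
        repro = ReproductionParams(f=0.7, p=1 - 1e-12, q=1e-12)
        rec = _cd_record(2015, [30, 120, 300], [1, 1, 1])
        ll = cd_loglik([rec], repro, CONST(0.0),
                       HazardModifiers(gamma_d=0.0))
        assert ll == pytest.approx(np.log(0.7), abs=1e-9)

    def test_single_detection_single_path(self):
        # q ~ 0: P(detected at t) = f * S_c(t) * A(t) * p
        repro = ReproductionParams(f=0.7, p=0.85, q=1e-14)
        gamma = 6.0
        mods = HazardModifiers(gamma_d=gamma)
        params = CONST(0.4)
        rec = _cd_record(2015, [330], [1])
        t = seasons.years_between(seasons.birth_pulse_date(2015),
                                  rec.observations[0].date)
        want = 0.7 * calf_survivorship(params, mods, 2015, t) * \
            dissociation_probability(gamma, t) * 0.85
        assert cd_loglik([rec], repro, params, mods) == \
            pytest.approx(np.log(want), rel=1e-9)

    @pytest.mark.parametrize("n_obs", [1, 2, 3, 4, 5, 6])
    def test_forward_equals_enumeration(self, n_obs):
        rng = np.random.default_rng(n_obs)
        offs = np.sort(rng.choice(np.arange(10, 360), size=n_obs,
                                  replace=False))
        dets = rng.integers(0, 2, size=n_obs)
        rec = _cd_record(2015 + n_obs % 2, offs, dets)
        fast = cd_loglik([rec], self.REPRO, self.PARAMS, self.MODS)
        slow = _enumeration_loglik(rec, self.REPRO, self.PARAMS, self.MODS)
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_forward_mass_is_probability(self):
        rng = np.random.default_rng(9)
        recs = [_cd_record(2015, np.sort(rng.choice(np.arange(5, 360), 8,
                                                    replace=False)),
                           rng.integers(0, 2, 8), cow_id=f"C{i}")
                for i in range(5)]
        ll = cd_loglik(recs, self.REPRO, self.PARAMS, self.MODS)
        assert -np.inf < ll < 0.0

    def test_additive_over_records(self):
        r1 = _cd_record(2015, [50, 200], [1, 0], "C1")
        r2 = _cd_record(2016, [80, 310], [0, 0], "C2")
        both = cd_loglik([r1, r2], self.REPRO, self.PARAMS, self.MODS)
        split = (cd_loglik([r1], self.REPRO, self.PARAMS, self.MODS)
                 + cd_loglik([r2], self.REPRO, self.PARAMS, self.MODS))
        assert both == pytest.approx(split, rel=1e-12)

    def test_observation_outside_calf_year_rejected(self):
        pulse = seasons.birth_pulse_date(2015)
        with pytest.raises(ValueError):
            CalfDetectionRecord("C1", 2015, [
                CalfObservation(pulse - dt.timedelta(days=5), True)])


class TestFirstYearSurvivorship:
    def test_matches_closed_form_without_modifiers(self):
        p = SilerParams(1.2, 3.0, 0.08, 0.01, 0.3)
        got = first_year_survivorship(p, HazardModifiers())
        want = np.exp(-siler_cumulative_hazard(p, 1.0))
        assert got == pytest.approx(want, rel=1e-10)

    def test_wet_season_lowers_it(self):
        p = SilerParams(1.2, 3.0, 0.08, 0.01, 0.3)
        base = first_year_survivorship(p, HazardModifiers())
        wet = first_year_survivorship(p, HazardModifiers(beta_s=0.5))
        assert wet < base
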