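"""Synthetic-data generator: determinism, rates, and stream consistency."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from wildemo import seasons
from wildemo.likelihoods import cc_loglik, cd_loglik, hc_loglik
from wildemo.records import ReproductionParams
from wildemo.siler import HazardModifiers, SilerParams
from wildemo.simulate import (DEFAULT_MODIFIERS, DEFAULT_SILER,
                              SimulationScenario, simulate_calf_histories,
                              simulate_cows, simulate_herd_counts,
                              simulate_observation_set)

ZERO_HAZARD = SilerParams(0, 1, 0, 0, 1)


def _scenario(**kw):
    return dataclasses.replace(SimulationScenario(), **kw)


class TestSimulateCows:
    def test_zero_hazard_no_deaths(self):
        sc = _scenario(params=ZERO_HAZARD,
                       mods=HazardModifiers(gamma_d=40.0),
                       poaching_rate=0.0, seed=3)
        cows, truth = simulate_cows(sc)
        assert not any(c.died for c in cows)
        assert (truth.cows["fate"] == "censored").all()

    def test_constant_hazard_death_count_in_binomial_bounds(self):
        # ~500 cow-years at hazard 0.15/yr: the realized death count must
        # sit inside the 99% envelope of its binomial expectation
        h = 0.15
        sc = _scenario(params=SilerParams(0, 1, h, 0, 1),
                       mods=HazardModifiers(), poaching_rate=0.0,
                       n_initial_cows=120, topup_size=15,
                       collar_life_years=50.0, seed=11)
        cows, truth = simulate_cows(sc)
        exposure = np.array([
            seasons.years_between(c.entry_date,
                                  c.found_dead_date or c.last_alive_date)
            for c in cows])
        assert exposure.sum() > 400
        deaths = sum(c.died for c in cows)
        p_death = 1 - np.exp(-h * exposure.mean())
        n = len(cows)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p_death)
        assert lo <= deaths <= hi

    def test_seed_determinism(self):
        sc = _scenario(seed=5)
        a, _ = simulate_cows(sc)
        b, _ = simulate_cows(sc)
        assert [c.cow_id for c in a] == [c.cow_id for c in b]
        assert all(x.events == y.events and
                   x.found_dead_date == y.found_dead_date
                   for x, y in zip(a, b))
        c, _ = simulate_cows(_scenario(seed=6))
        assert any(x.events != y.events for x, y in zip(a, c))

    def test_entry_ages_within_range(self):
        cows, _ = simulate_cows(_scenario(seed=1))
        ages = [c.entry_age for c in cows]
        lo, hi = SimulationScenario().entry_age_range
        assert min(ages) >= lo and max(ages) <= hi

    def test_poaching_fraction_responds_to_rate(self):
        _, t0 = simulate_cows(_scenario(poaching_rate=0.0, seed=2))
        _, t1 = simulate_cows(_scenario(poaching_rate=0.5, seed=2))
        assert (t0.cows["fate"] == "poached").sum() == 0
        assert (t1.cows["fate"] == "poached").sum() > 10

    def test_death_interval_follows_last_sighting(self):
        cows, _ = simulate_cows(_scenario(seed=4))
        for c in cows:
            if c.died:
                assert c.found_dead_date > c.last_alive_date


class TestSimulateHerdCounts:
    def test_zero_fecundity_means_no_calves(self):
        sc = _scenario(repro=ReproductionParams(f=1e-9), seed=3)
        _, truth = simulate_cows(sc)
        counts = simulate_herd_counts(sc, truth)
        assert sum(h.n_calves for h in counts) == 0

    def test_mean_calf_fraction_near_expectation(self):
        # law of large numbers: with the default rates the post-window mean
        # calf fraction sits near f*S1/(1+f*S1) ~ 0.28 at t = 1
        sc = _scenario(herd_counts_per_year=400, classified_mean=57, seed=8)
        _, truth = simulate_cows(sc)
        counts = simulate_herd_counts(sc, truth)
        late = [h for h in counts if 0.85 < h.time_since_pulse < 1.0]
        frac = (sum(h.n_calves for h in late)
                / sum(h.n_calves + h.n_cows for h in late))
        r = 0.68 * 0.56
        assert frac == pytest.approx(r / (1 + r), abs=0.02)

    def test_calving_window_counts_generated_then_excluded(self):
        sc = _scenario(seed=9)
        data, _ = simulate_observation_set(sc)
        n_window = data.validation_log["herd_counts_excluded_calving_window"]
        assert n_window > 0
        assert all(not seasons.in_calving_window(h.date)
                   for h in data.herd_counts)
        assert (data.validation_log["herd_counts_total"]
                == data.validation_log["herd_counts_retained"]
                + n_window
                + data.validation_log["herd_counts_excluded_zero_classified"])


class TestSimulateCalfHistories:
    def test_perfect_detection_immortal_calves(self):
        # p ~ 1, q ~ 0, no calf mortality or dissociation: each cow-year
        # sequence is constant, and the all-detected fraction estimates f
        sc = _scenario(params=ZERO_HAZARD,
                       mods=HazardModifiers(gamma_d=0.0),
                       repro=ReproductionParams(f=0.68, p=1 - 1e-12, q=1e-12),
                       poaching_rate=0.0, n_initial_cows=300, seed=12)
        cows, truth = simulate_cows(sc)
        recs, truth = simulate_calf_histories(sc, truth, cows)
        seqs = [np.array([o.detected for o in r.observations]) for r in recs]
        assert all(s.all() or not s.any() for s in seqs)
        frac = np.mean([s.all() for s in seqs])
        se = np.sqrt(0.68 * 0.32 / len(seqs))
        assert frac == pytest.approx(0.68, abs=4 * se)

    def test_detection_marginal_matches_forward_model(self):
        # empirical per-observation detection frequency vs the hidden-state
        # marginal f*S_c(t)*A(t)*p + (1-that)*q, binned by age
        from wildemo.likelihoods import (calf_survivorship,
                                         dissociation_probability)
        sc = _scenario(n_initial_cows=400, topup_size=0, n_years=2,
                       poaching_rate=0.0, sighting_success=1.0, seed=13)
        cows, truth = simulate_cows(sc)
        recs, _ = simulate_calf_histories(sc, truth, cows)
        obs = [(seasons.years_between(seasons.birth_pulse_date(r.calf_year),
                                      o.date), o.detected, r.calf_year)
               for r in recs for o in r.observations]
        ts = np.array([t for t, _, _ in obs])
        det = np.array([d for _, d, _ in obs], dtype=float)
        cys = np.array([c for _, _, c in obs])
        for lo, hi in ((0.1, 0.3), (0.4, 0.6), (0.8, 1.0)):
            m = (ts > lo) & (ts < hi)
            if m.sum() < 200:
                continue
            t_mid = ts[m].mean()
            cy = int(np.bincount(cys[m]).argmax())
            p_present = (sc.repro.f
                         * calf_survivorship(sc.params, sc.mods, cy, t_mid)
                         * dissociation_probability(sc.mods.gamma_d, t_mid))
            want = p_present * sc.repro.p + (1 - p_present) * sc.repro.q
            se = np.sqrt(want * (1 - want) / m.sum())
            assert det[m].mean() == pytest.approx(want, abs=5 * se + 0.01)

    def test_dead_cow_calf_observations_cease(self, default_obs):
        data, truth = default_obs
        end = dict(zip(truth.cows["cow_id"], truth.cows["end_date"]))
        for rec in data.calf_obs:
            for o in rec.observations:
                assert o.date < end[rec.cow_id]


class TestGeneratorLikelihoodConsistency:
    def test_loglik_peaks_at_generating_parameters(self):
        # self-consistency of the generative triple: at large n the average
        # log-likelihood at the truth beats +-20% parameter perturbations
        sc = _scenario(n_initial_cows=250, topup_size=25, seed=21)
        data, truth = simulate_observation_set(sc)
        repro = sc.repro
        ll_true = (cc_loglik(data.cows, sc.params, sc.mods)
                   + hc_loglik(data.herd_counts, repro, sc.params, sc.mods)
                   + cd_loglik(data.calf_obs, repro, sc.params, sc.mods))
        for fac in (0.8, 1.2):
            params = SilerParams(sc.params.a1 * fac, sc.params.b1,
                                 sc.params.a2 * fac, sc.params.a3 * fac,
                                 sc.params.b3)
            repro2 = ReproductionParams(
                f=min(0.95, repro.f * fac), p=repro.p, q=repro.q)
            ll = (cc_loglik(data.cows, params, sc.mods)
                  + hc_loglik(data.herd_counts, repro2, params, sc.mods)
                  + cd_loglik(data.calf_obs, repro2, params, sc.mods))
            assert ll < ll_true

    def test_observation_set_streams_share_truth(self, default_obs):
        data, truth = default_obs
        cow_ids = {c.cow_id for c in data.cows}
        assert {r.cow_id for r in data.calf_obs} <= cow_ids
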