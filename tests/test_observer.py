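"""Generative observer: percept statistics, sessions, cohorts, eye traces."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from speedprior.bayes_model import predicted_ratio
from speedprior.design import build_design
from speedprior.observer import (
    CohortSpec,
    ObserverParams,
    make_cohort,
    percept_sample,
    response_probability,
    shrinkage_weight,
    simulate_eye_trace,
    simulate_session,
    simulate_trial,
)
from speedprior.psychometrics import aggregate, fit_cumulative_gaussian


def params(Q=10.0, k=0.1, sA=0.8, sB=1.4, oid="obs"):
    return ObserverParams(observer_id=oid, Q=Q, k=k, sigma_lA=sA, sigma_lB=sB)


class TestCohort:
    def test_degenerate_spread_gives_constant_trait(self):
        cohort = make_cohort(CohortSpec(n_observers=20, Q_mean=16, Q_sd=0), seed=0)
        assert all(p.Q == 16 for p in cohort)

    def test_trait_moments_match_truncated_normal(self):
        # oracle: analytic moments of N(15.6, 7.7^2) truncated to [0, 50]
        spec = CohortSpec(n_observers=10_000, Q_mean=15.6, Q_sd=7.7)
        cohort = make_cohort(spec, seed=1)
        q = np.array([p.Q for p in cohort])
        a = (0 - 15.6) / 7.7
        b = (50 - 15.6) / 7.7
        mean_th, var_th = sps.truncnorm.stats(a, b, loc=15.6, scale=7.7, moments="mv")
        assert abs(q.mean() - mean_th) < 4 * np.sqrt(var_th / len(q)) + 0.05
        assert abs(q.std() - np.sqrt(var_th)) < 0.2

    def test_traits_are_integers_in_range(self):
        cohort = make_cohort(CohortSpec(n_observers=500), seed=2)
        q = np.array([p.Q for p in cohort])
        assert np.all(q == np.rint(q))
        assert q.min() >= 0 and q.max() <= 50

    def test_same_seed_identical_cohort(self):
        spec = CohortSpec(n_observers=10)
        assert make_cohort(spec, seed=5) == make_cohort(spec, seed=5)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_observers=0)
        with pytest.raises(ValueError):
            CohortSpec(sigma_lA_range=(0.0, 1.0))


class TestPerceptSample:
    def test_collapsed_prior_yields_zero_percept(self, rng):
        out = percept_sample(np.full(100, 8.0), 2.0, 0.0, rng)
        assert np.all(out == 0.0)

    def test_flat_prior_limit_is_unbiased(self, rng):
        out = percept_sample(np.full(100_000, 8.0), 2.0, 1e12, rng)
        assert abs(out.mean() - 8.0) < 0.03

    def test_shrinkage_closed_form(self, rng):
        # w = 4 / (4 + 4) = 1/2, so E[percept] = 4 and SD = 1
        out = percept_sample(np.full(100_000, 8.0), 2.0, 4.0, rng)
        assert abs(out.mean() - 4.0) < 0.02
        assert abs(out.std() - 1.0) < 0.02

    def test_nonpositive_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            percept_sample(8.0, 0.0, 1.0, rng)


class TestTrialSimulation:
    def test_equal_speeds_equal_conditions_is_coin_flip(self, rng):
        p = params()
        trial = {"trial_type": "AA", "test_speed": 8.0, "standard_speed": 8.0}
        hits = sum(simulate_trial(trial, p, rng)["response"] for _ in range(4000))
        assert sps.binomtest(hits, 4000, 0.5).pvalue > 1e-3

    def test_symmetric_conditions_give_unit_pse_ratio(self):
        # sigma_lA == sigma_lB: the analytic 50% point of AB trials is the standard
        p = params(sA=1.0, sB=1.0)
        prob = response_probability(8.0, 8.0, 1.0, 1.0, p.prior_variance)
        assert prob == pytest.approx(0.5)

    def test_ab_pse_matches_model_equation(self, rng):
        # kQ = 1, implied thresholds delta_A = 1, delta_B = 2:
        # ratio = (1 + 0.5) / (1 + 2) = 0.5, so PSE = 4 at an 8 deg/s standard
        p = params(Q=10, k=0.1, sA=1 / np.sqrt(2), sB=np.sqrt(2))
        expected = predicted_ratio(p.k, p.Q, 1.0, 2.0)
        assert expected == pytest.approx(0.5)
        prob_at_pse = response_probability(8 * expected, 8.0, p.sigma_lA,
                                           p.sigma_lB, p.prior_variance)
        assert prob_at_pse == pytest.approx(0.5, abs=1e-12)
        # and by brute simulation of sessions
        design = build_design("af", reps_per_speed=60)
        trials = simulate_session(design, p, rng)
        fit = fit_cumulative_gaussian(aggregate(trials, "AB"))
        assert fit.mu / 8.0 == pytest.approx(0.5, abs=0.06)

    def test_unmapped_trial_type_rejected(self, rng):
        with pytest.raises(ValueError, match="unmapped trial type"):
            simulate_trial({"trial_type": "BA", "test_speed": 1, "standard_speed": 1},
                           params(), rng)


class TestSession:
    def test_full_af_session_answered(self, af_design):
        trials = simulate_session(af_design, params(), 0)
        assert len(trials) == 210
        assert trials["response"].notna().all()

    def test_same_seed_identical_responses(self, af_design):
        a = simulate_session(af_design, params(), 9)
        b = simulate_session(af_design, params(), 9)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_limit_is_step_function(self, af_design):
        p = params(sA=1e-9, sB=1e-9)
        trials = simulate_session(af_design, p, 0)
        aa = trials[(trials["trial_type"] == "AA") & (trials["test_speed"] != 8.0)]
        assert (aa["response"] == (aa["test_speed"] > 8.0)).all()

    def test_aa_psychometric_sd_is_sqrt2_sigma(self):
        """The SDT mapping: fitted AA threshold ~ sqrt(2) * sigma_lA."""
        p = params(sA=0.9)
        design = build_design("af", reps_per_speed=400,
                              trial_types=("AA",),
                              test_speeds_by_type={"AA": tuple(np.linspace(4, 12, 7))})
        fit = fit_cumulative_gaussian(aggregate(simulate_session(design, p, 4), "AA"))
        assert fit.sigma == pytest.approx(np.sqrt(2) * 0.9, rel=0.06)

    def test_increasing_prior_variance_moves_ratio_toward_unity(self):
        # analytic AB ratio implied by the generator, on a kQ grid
        sA, sB = 0.8, 1.6
        kq = np.linspace(0.0, 50.0, 200)
        wA = shrinkage_weight(sA, kq)
        wB = shrinkage_weight(sB, kq)
        with np.errstate(invalid="ignore"):
            ratio = np.where(wA > 0, wB / wA, sA**2 / sB**2)
        assert np.all(np.diff(ratio) >= -1e-12)
        assert ratio[-1] < 1 and ratio[-1] > 0.95 * (50 + sA**2) / (50 + sB**2)


class TestEyeTrace:
    def test_pure_pursuit_ramp(self):
        series = simulate_eye_trace("pursuit", 8.0, 1.0, 0.0, seed=0)
        assert len(series.time) == 1250
        v = np.diff(series.x) * 1000.0
        assert np.allclose(v, 8.0, atol=1e-9)

    def test_fixation_is_stationary(self):
        series = simulate_eye_trace("fixation", 8.0, 1.0, 0.0, seed=0)
        assert np.allclose(series.x, series.x[0] * np.ones_like(series.x), atol=1e-12)

    def test_blink_marks_invalid_run(self):
        series = simulate_eye_trace("pursuit", 8.0, 1.0, 0.0, blink_prob=1.0, seed=1)
        assert (~series.valid).sum() >= 100  # at least 100 ms at 1000 Hz

    def test_determinism(self):
        a = simulate_eye_trace("pursuit", 8.0, 0.9, 0.5, saccade_rate=2.0, seed=3)
        b = simulate_eye_trace("pursuit", 8.0, 0.9, 0.5, saccade_rate=2.0, seed=3)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.valid, b.valid)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_eye_trace("pursuit", 8.0, 1.0, 0.0, duration_s=-1.0)
        with pytest.raises(ValueError):
            simulate_eye_trace("glance", 8.0, 1.0, 0.0)
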