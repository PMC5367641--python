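"""Probit fitting, effect ratios and the cohort exclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from speedprior.design import build_design
from speedprior.oculomotor import OculomotorSummary
from speedprior.psychometrics import (
    ExclusionConfig,
    ObserverSummary,
    PsychometricData,
    aggregate,
    apply_exclusions,
    effect_ratio,
    fit_cumulative_gaussian,
    summaries_to_frame,
)

LEVELS = np.linspace(4, 12, 7)


def binomial_data(mu, sigma, n_per_level, seed=0, levels=LEVELS):
    rng = np.random.default_rng(seed)
    p = norm.cdf((levels - mu) / sigma)
    k = rng.binomial(n_per_level, p)
    return PsychometricData(levels, k, np.full(len(levels), n_per_level))


class TestAggregate:
    def test_counts_per_level(self, af_design):
        from speedprior.observer import ObserverParams, simulate_session

        p = ObserverParams("o", 10, 0.1, 0.8, 1.4)
        trials = simulate_session(af_design, p, 0)
        data = aggregate(trials, "AB")
        assert len(data.levels) == 7
        assert (data.n_total == 10).all()
        assert data.n_total.sum() == (trials["trial_type"] == "AB").sum()

    def test_missing_type_raises(self, af_design):
        from speedprior.design import enumerate_trials

        trials = enumerate_trials(af_design, seed=0)
        trials["response"] = True
        with pytest.raises(ValueError, match="no trials of type"):
            aggregate(trials[trials["trial_type"] != "AB"], "AB")


class TestFit:
    def test_recovers_generating_parameters(self):
        data = binomial_data(8.0, 1.5, 10_000, seed=1)
        fit = fit_cumulative_gaussian(data)
        assert fit.converged
        assert fit.mu == pytest.approx(8.0, abs=0.05)
        assert fit.sigma == pytest.approx(1.5, abs=0.05)

    def test_symmetric_data_centre_exact(self):
        counts = np.array([0, 1, 3, 5, 7, 9, 10])
        data = PsychometricData(LEVELS, counts, np.full(7, 10))
        fit = fit_cumulative_gaussian(data)
        assert fit.mu == pytest.approx(8.0, abs=1e-6)

    def test_flat_data_flagged_not_raised(self):
        data = PsychometricData(LEVELS, np.full(7, 5), np.full(7, 10))
        fit = fit_cumulative_gaussian(data)
        assert not fit.converged

    @pytest.mark.parametrize("value", [0, 10])
    def test_degenerate_all_identical_flagged(self, value):
        data = PsychometricData(LEVELS, np.full(7, value), np.full(7, 10))
        assert not fit_cumulative_gaussian(data).converged

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="at least 3 levels"):
            fit_cumulative_gaussian(PsychometricData([1, 2], [0, 5], [5, 5]))

    def test_matches_brute_force_grid_search(self):
        """ML optimum agrees with an exhaustive (mu, sigma) likelihood grid."""
        data = binomial_data(7.4, 2.1, 25, seed=7)
        fit = fit_cumulative_gaussian(data)
        mus = np.linspace(4, 12, 321)
        sigmas = np.linspace(0.2, 6, 300)
        M, S = np.meshgrid(mus, sigmas)
        P = np.clip(norm.cdf((data.levels - M[..., None]) / S[..., None]),
                    1e-12, 1 - 1e-12)
        ll = (data.n_test_faster * np.log(P)
              + (data.n_total - data.n_test_faster) * np.log1p(-P)).sum(-1)
        i = np.unravel_index(np.argmax(ll), ll.shape)
        assert fit.mu == pytest.approx(M[i], abs=(mus[1] - mus[0]))
        assert fit.sigma == pytest.approx(S[i], abs=(sigmas[1] - sigmas[0]))
        assert fit.log_likelihood >= ll[i] - 1e-9

    def test_matches_statsmodels_probit_glm(self):
        """Independent route: binomial GLM with probit link."""
        import statsmodels.api as sm

        data = binomial_data(8.6, 1.2, 40, seed=3)
        fit = fit_cumulative_gaussian(data)
        endog = np.column_stack([data.n_test_faster,
                                 data.n_total - data.n_test_faster])
        exog = sm.add_constant(data.levels)
        glm = sm.GLM(endog, exog,
                     family=sm.families.Binomial(sm.families.links.Probit())).fit()
        intercept, slope = glm.params
        assert fit.mu == pytest.approx(-intercept / slope, rel=1e-4)
        assert fit.sigma == pytest.approx(1.0 / slope, rel=1e-4)

    @given(shift=st.floats(min_value=-20, max_value=20))
    def test_translation_equivariance(self, shift):
        """Shifting all levels shifts the PSE and leaves the threshold alone."""
        base = binomial_data(8.0, 1.5, 50, seed=11)
        fit0 = fit_cumulative_gaussian(base)
        shifted = PsychometricData(base.levels + shift, base.n_test_faster,
                                   base.n_total)
        fit1 = fit_cumulative_gaussian(shifted)
        assert fit1.mu - fit0.mu == pytest.approx(shift, abs=1e-5)
        assert fit1.sigma == pytest.approx(fit0.sigma, abs=1e-5)


class TestEffectRatio:
    def test_pursuit_experiment_formula(self, af_design):
        fit = fit_cumulative_gaussian(binomial_data(6.0, 1.0, 1000, seed=0,
                                                    levels=np.linspace(0, 8, 7)))
        assert effect_ratio(fit, af_design) == pytest.approx(6.0 / 8.0, abs=0.02)

    def test_contrast_experiment_formula(self, contrast_design):
        fit = fit_cumulative_gaussian(binomial_data(2.5, 0.4, 1000, seed=0,
                                                    levels=np.linspace(1, 4, 9)))
        assert effect_ratio(fit, contrast_design) == pytest.approx(2.0 / 2.5, abs=0.02)

    def test_nonconverged_fit_rejected(self, af_design):
        flat = fit_cumulative_gaussian(
            PsychometricData(LEVELS, np.full(7, 5), np.full(7, 10)))
        with pytest.raises(ValueError):
            effect_ratio(flat, af_design)


def make_summary(oid="o", Q=15, dA=1.0, dB=2.0, pse=6.0, ratio=0.75,
                 ab=True, eye=True, fix=0.5, gain=0.95, lost=0.05):
    eye_summary = OculomotorSummary(
        mean_fixation_speed=fix, mean_pursuit_speed=gain * 8.0,
        pursuit_gain=gain, fraction_samples_lost=lost,
    ) if eye else None
    return ObserverSummary(observer_id=oid, Q=Q, delta_A=dA, delta_B=dB,
                           pse_ab=pse, ratio_measured=ratio, ab_converged=ab,
                           eye=eye_summary)


class TestExclusions:
    def test_compliant_cohort_untouched(self):
        cohort = [make_summary(oid=f"o{i}") for i in range(10)]
        included, excluded = apply_exclusions(cohort, "af")
        assert len(included) == 10 and not excluded

    def test_flat_ab_function(self):
        cohort = [make_summary(oid="bad", ab=False)] + [make_summary(oid=f"o{i}") for i in range(3)]
        _, excluded = apply_exclusions(cohort, "af")
        assert [s.observer_id for s in excluded] == ["bad"]
        assert "50%" in excluded[0].exclusion_reason

    def test_fixation_speed_rule(self):
        cohort = [make_summary(oid="bad", fix=2.5)] + [make_summary(oid=f"o{i}") for i in range(3)]
        _, excluded = apply_exclusions(cohort, "af")
        assert excluded[0].exclusion_reason == "fixation eye speed > 2 deg/s"

    def test_pursuit_gain_rule(self):
        cohort = [make_summary(oid="bad", gain=0.55)] + [make_summary(oid=f"o{i}") for i in range(3)]
        _, excluded = apply_exclusions(cohort, "af")
        assert excluded[0].exclusion_reason == "pursuit gain < 0.6"

    def test_sample_loss_rule(self):
        cohort = [make_summary(oid="bad", lost=0.6)] + [make_summary(oid=f"o{i}") for i in range(3)]
        _, excluded = apply_exclusions(cohort, "af")
        assert excluded[0].exclusion_reason == "> 50% eye samples lost"

    def test_first_matching_rule_wins(self):
        # violates both the fixation rule (2) and the gain rule (3)
        cohort = [make_summary(oid="bad", fix=3.0, gain=0.4)] + [make_summary(oid=f"o{i}") for i in range(3)]
        _, excluded = apply_exclusions(cohort, "af")
        assert excluded[0].exclusion_reason == "fixation eye speed > 2 deg/s"

    def test_contrast_pse_outlier_rule(self):
        cohort = [make_summary(oid=f"o{i}", eye=False, pse=2.5 + 0.01 * i)
                  for i in range(12)]
        pses = np.array([s.pse_ab for s in cohort])
        outlier = pses.mean() + 20 * pses.std(ddof=1)
        cohort.append(make_summary(oid="out", eye=False, pse=outlier))
        included, excluded = apply_exclusions(cohort, "contrast")
        assert [s.observer_id for s in excluded] == ["out"]
        assert "SDs above cohort mean" in excluded[0].exclusion_reason

    def test_outlier_rule_not_applied_to_pursuit_experiment(self):
        cohort = [make_summary(oid=f"o{i}", pse=6.0) for i in range(12)]
        cohort.append(make_summary(oid="out", pse=60.0))
        included, _ = apply_exclusions(cohort, "af")
        assert len(included) == 13

    def test_missing_eye_metrics_error_for_pursuit_cohort(self):
        cohort = [make_summary(oid="o", eye=False)]
        with pytest.raises(ValueError, match="eye metrics required"):
            apply_exclusions(cohort, "af")

    def test_input_summaries_not_mutated(self):
        bad = make_summary(oid="bad", gain=0.4)
        apply_exclusions([bad, make_summary()], "af")
        assert not bad.excluded

    def test_frame_export_includes_eye_columns(self):
        frame = summaries_to_frame([make_summary()])
        assert "pursuit_gain" in frame.columns and len(frame) == 1
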