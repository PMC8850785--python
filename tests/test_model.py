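"""Threshold-distribution model: CDF, likelihood, MLE, tests, selection."""

import math

import numpy as np
import pytest
from scipy import stats

import painlimits as pl
from painlimits import reference
from painlimits.censoring import Sample, SubjectMean
from painlimits.errors import (
    DegenerateTestError,
    IdentifiabilityError,
    InvalidArgumentError,
    LikelihoodDegenerateError,
)
from painlimits.model import AFTFit, CensoredData, _loglik

from conftest import make_sample


class TestExpandedCdf:
    def test_median_at_shifted_location(self):
        y = math.exp(4.22 + 0.7 * 0.5)
        assert pl.expanded_cdf(y, 0.7, 4.22, 0.5, 0.46) == pytest.approx(0.5)

    def test_upper_quartile_inverse(self):
        assert pl.expanded_cdf(112.77, 0.0, 4.22, 0.0, 0.46) == \
            pytest.approx(0.75, abs=1e-4)

    def test_limits_at_domain_ends(self):
        assert pl.expanded_cdf(1e-12, 0.0, 4.22, 0.0, 0.46) < 1e-9
        assert pl.expanded_cdf(1e12, 0.0, 4.22, 0.0, 0.46) > 1 - 1e-9

    def test_strictly_increasing_in_y(self):
        y = np.linspace(1.0, 500.0, 200)
        f = pl.expanded_cdf(y, 0.7, 4.0, 0.4, 0.3)
        assert np.all(np.diff(f) > 0)

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pl.expanded_cdf(0.0, 0.0, 4.0, 0.0, 0.3)
        with pytest.raises(InvalidArgumentError):
            pl.expanded_cdf(-5.0, 0.0, 4.0, 0.0, 0.3)


class TestLogLikelihood:
    def _sample_one(self, obs):
        member = SubjectMean("S1", 0, obs if np.isfinite(obs) else 1.0, 1)
        return Sample("12", "pinching", "blunt", [member])

    def test_exact_at_median_closed_form(self):
        beta0, alpha = 4.0, 0.37
        sample = self._sample_one(math.exp(beta0))
        value = pl.log_likelihood((beta0, 0.0, alpha), sample)
        assert value == pytest.approx(-math.log(4 * alpha * math.exp(beta0)))

    def test_right_censored_at_median(self):
        member = SubjectMean("S1", 0, math.exp(4.0), 1, right_censored=True)
        sample = Sample("12", "pinching", "blunt", [member])
        value = pl.log_likelihood((4.0, 0.0, 0.3), sample)
        assert value == pytest.approx(math.log(0.5))

    def test_interval_mass(self):
        # interval with F(R) = 0.8, F(L) = 0.3 contributes log 0.5
        beta0, alpha = 4.0, 0.3
        L = math.exp(beta0 + alpha * math.log(0.3 / 0.7))
        R = math.exp(beta0 + alpha * math.log(0.8 / 0.2))
        obs = pl.IntervalObservation(L, R, "interval", subject_id="S1")
        member = SubjectMean("S1", 0, obs.imputed_y, 1)
        sample = Sample("12", "pinching", "blunt", [member],
                        observations=[obs])
        value = pl.log_likelihood((beta0, 0.0, alpha), sample,
                                  mode="interval")
        assert value == pytest.approx(math.log(0.5), abs=1e-9)

    def test_degenerate_parameters_raise(self):
        sample = self._sample_one(50.0)
        with pytest.raises(LikelihoodDegenerateError):
            pl.log_likelihood((4.0, 0.0, -1.0), sample)


class TestFitAft:
    def test_parameter_recovery_within_three_se(self):
        sample = make_sample(4.0, 0.5, 0.3, n=400, male_fraction=0.5, seed=21)
        fit = pl.fit_aft(sample)
        for value, truth, idx in [(fit.beta0, 4.0, 0), (fit.beta1, 0.5, 1),
                                  (fit.alpha, 0.3, 2)]:
            se = math.sqrt(fit.covariance[idx, idx])
            assert abs(value - truth) < 3 * se

    def test_constrained_fit_is_nested(self):
        sample = make_sample(4.0, 0.5, 0.3, n=80, seed=3)
        full = pl.fit_aft(sample)
        reduced = pl.fit_aft(sample, constrain_beta1_zero=True)
        assert reduced.beta1 == 0.0
        assert reduced.log_likelihood <= full.log_likelihood + 1e-9

    def test_grid_oracle_finds_no_better_likelihood(self):
        # brute-force 3-D grid around the optimizer's solution
        sample = make_sample(4.0, 0.4, 0.3, n=30, seed=5)
        fit = pl.fit_aft(sample)
        data = CensoredData.from_sample(sample)
        best = -np.inf
        for b0 in np.linspace(fit.beta0 - 0.5, fit.beta0 + 0.5, 21):
            for b1 in np.linspace(0.0, 1.0, 21):
                for a in np.linspace(0.1, 0.8, 21):
                    best = max(best, _loglik(b0, b1, a, data, "log-logistic"))
        assert fit.log_likelihood >= best - 1e-4

    def test_single_gender_unconstrained_rejected(self):
        sample = make_sample(4.0, 0.0, 0.3, n=20, male_fraction=1.0, seed=7)
        with pytest.raises(IdentifiabilityError):
            pl.fit_aft(sample)
        fit = pl.fit_aft(sample, constrain_beta1_zero=True)
        assert fit.constrained

    def test_tiny_sample_rejected(self):
        sample = make_sample(4.0, 0.0, 0.3, n=2, seed=1)
        with pytest.raises(InvalidArgumentError):
            pl.fit_aft(sample)

    def test_interval_mode_agrees_with_lifelines(self):
        # independent cross-check: interval-censored log-logistic AFT
        # fitted by lifelines on the same brackets
        pytest.importorskip("lifelines")
        import pandas as pd
        from lifelines import LogLogisticAFTFitter

        rng = np.random.default_rng(17)
        spec = pl.ThresholdSpec(12, "pinching", "blunt", 4.0, 0.4, 0.3)
        members, observations = [], []
        for i in range(150):
            g = i % 2
            y = pl.draw_threshold(spec, g, rng)
            lo = y * rng.uniform(0.7, 0.95)
            hi = y * rng.uniform(1.05, 1.4)
            obs = pl.IntervalObservation(lo, hi, "interval",
                                         subject_id=f"S{i:03d}")
            observations.append(obs)
            members.append(SubjectMean(f"S{i:03d}", g, obs.imputed_y, 1))
        sample = Sample("12", "pinching", "blunt", members,
                        observations=observations)
        fit = pl.fit_aft(sample, mode="interval")

        df = pd.DataFrame({
            "lb": [o.L for o in observations],
            "ub": [o.R for o in observations],
            "male": [m.gender_code for m in members],
        })
        ll = LogLogisticAFTFitter()
        ll.fit_interval_censoring(df, lower_bound_col="lb", upper_bound_col="ub")
        beta0_ll = ll.params_[("alpha_", "Intercept")]
        beta1_ll = ll.params_[("alpha_", "male")]
        alpha_ll = 1.0 / math.exp(ll.params_[("beta_", "Intercept")])
        assert fit.beta0 == pytest.approx(beta0_ll, abs=1e-3)
        assert fit.beta1 == pytest.approx(beta1_ll, abs=1e-3)
        assert fit.alpha == pytest.approx(alpha_ll, abs=1e-3)


class TestWaldTest:
    def _fit(self, beta1, se, n=40):
        cov = np.zeros((3, 3))
        cov[1, 1] = se ** 2
        return AFTFit(family="log-logistic", beta0=4.0, beta1=beta1,
                      alpha=0.3, covariance=cov, log_likelihood=0.0,
                      n_used=n, constrained=False)

    def test_zero_effect_gives_p_one(self):
        assert pl.wald_p_value(self._fit(0.0, 0.1)) == pytest.approx(1.0)

    def test_effect_at_critical_value_large_sample(self):
        # the small-sample correction vanishes asymptotically: an effect
        # of 1.96 standard errors sits at p = 0.05
        assert pl.wald_p_value(self._fit(1.96 * 0.1, 0.1, n=100_000)) == \
            pytest.approx(0.05, abs=1e-3)

    def test_small_sample_correction_is_conservative(self):
        p_small = pl.wald_p_value(self._fit(1.96 * 0.1, 0.1, n=40))
        p_large = pl.wald_p_value(self._fit(1.96 * 0.1, 0.1, n=100_000))
        assert p_small > p_large

    def test_zero_se_rejected(self):
        with pytest.raises(DegenerateTestError):
            pl.wald_p_value(self._fit(0.5, 0.0))


class TestGenderRelevance:
    def test_three_significant_conditions_relevant(self):
        # 0.050 is not strictly below the significance level
        d = pl.gender_relevance((0.007, 0.050, 0.017, 0.020))
        assert d.relevant

    def test_no_significant_condition_not_relevant(self):
        assert not pl.gender_relevance((0.098, 0.455, 0.098, 0.214)).relevant

    def test_single_significant_condition_not_relevant(self):
        assert not pl.gender_relevance((0.04, 0.2, 0.2, 0.2)).relevant

    def test_published_relevance_flags_recovered(self):
        # applying the rule to the published per-condition p-values
        # reproduces the published per-location relevance column
        for row in reference.MEASURED_ROWS:
            ps = [reference.GENDER_P_VALUES[(row, load, contact)]
                  for load, contact in reference.CONDITIONS]
            decision = pl.gender_relevance(ps, row)
            assert decision.relevant == (row in reference.GENDER_RELEVANT_ROWS), row

    def test_p_value_count_bounds(self):
        with pytest.raises(InvalidArgumentError):
            pl.gender_relevance(())
        with pytest.raises(InvalidArgumentError):
            pl.gender_relevance((0.1,) * 5)


class TestSelectFamily:
    def test_lognormal_truth_selected(self):
        rng = np.random.default_rng(2)
        members = [SubjectMean(f"S{i}", i % 2,
                               float(np.exp(4.0 + 0.3 * rng.normal())), 1)
                   for i in range(500)]
        sample = Sample("12", "pinching", "blunt", members)
        assert pl.select_family(sample) == "log-normal"

    def test_too_small_sample_rejected(self):
        sample = make_sample(4.0, 0.0, 0.3, n=7, seed=1)
        with pytest.raises(InvalidArgumentError):
            pl.select_family(sample)


class TestFitRSquared:
    def _perfect_sample(self, fit, n=40):
        pp = (np.arange(1, n + 1) - 0.5) / n
        y = np.exp(fit.beta0 + fit.alpha * special_logit(pp))
        members = [SubjectMean(f"S{i}", 0, float(v), 1)
                   for i, v in enumerate(y)]
        return Sample("12", "pinching", "blunt", members)

    def test_data_at_model_quantiles_gives_unity(self):
        fit = AFTFit("log-logistic", 4.0, 0.0, 0.35, np.zeros((2, 2)),
                     0.0, 40, constrained=True)
        sample = self._perfect_sample(fit)
        assert pl.fit_r_squared(fit, sample) == pytest.approx(1.0, abs=1e-9)

    def test_sorted_pairing_beats_shuffled(self):
        fit = AFTFit("log-logistic", 4.0, 0.0, 0.35, np.zeros((2, 2)),
                     0.0, 40, constrained=True)
        sample = make_sample(4.0, 0.0, 0.35, n=40, seed=9)
        y = np.log([m.y_bar for m in sample.members])
        pp = (np.arange(1, 41) - 0.5) / 41
        q = fit.beta0 + fit.alpha * special_logit(pp)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(y)
        r_sorted = np.corrcoef(np.sort(y), q)[0, 1] ** 2
        r_shuffled = np.corrcoef(shuffled, q)[0, 1] ** 2
        assert r_shuffled < r_sorted


def special_logit(p):
    return np.log(np.asarray(p) / (1.0 - np.asarray(p)))


class TestModelInvariants:
    def test_cdf_quantile_round_trip(self):
        fits = pl.reference_fits()
        for fit in fits.values():
            for q in (0.1, 0.5, 0.75, 0.9):
                y = pl.quantile_limit(fit, q, 0.7)
                assert abs(pl.expanded_cdf(y, 0.7, fit.beta0, fit.beta1,
                                           fit.alpha) - q) < 1e-9

    def test_quantiles_monotone_in_q_and_gender(self):
        fit = pl.fit_from_params(4.0, 0.4, 0.3)
        qs = np.linspace(0.05, 0.95, 19)
        values = [pl.quantile_limit(fit, q, 0.5) for q in qs]
        assert np.all(np.diff(values) > 0)
        xs = np.linspace(0.0, 1.0, 11)
        values = [pl.quantile_limit(fit, 0.75, x) for x in xs]
        assert np.all(np.diff(values) > 0)

    def test_beta0_ci_coverage(self):
        # 95% Wald intervals for the intercept cover the truth at the
        # nominal rate over repeated synthetic samples
        hits = 0
        n_rep = 500
        for rep in range(n_rep):
            sample = make_sample(4.0, 0.5, 0.3, n=100, seed=40_000 + rep)
            fit = pl.fit_aft(sample)
            se = math.sqrt(fit.covariance[0, 0])
            hits += abs(fit.beta0 - 4.0) <= 1.96 * se
        assert 0.93 <= hits / n_rep <= 0.97

    def test_wald_and_lr_tests_agree(self):
        agree = 0
        n_rep = 100
        for rep in range(n_rep):
            sample = make_sample(4.0, 0.25, 0.3, n=200, seed=50_000 + rep)
            full = pl.fit_aft(sample)
            reduced = pl.fit_aft(sample, constrain_beta1_zero=True)
            lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
            p_lr = stats.chi2.sf(max(lr, 0.0), df=1)
            agree += (full.p_beta1 < 0.05) == (p_lr < 0.05)
        assert agree / n_rep >= 0.95
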