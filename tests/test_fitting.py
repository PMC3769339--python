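"""Least-squares and Bayesian estimation, AIC and nested-model comparison."""

import math

import numpy as np
import pytest
from scipy import special

from nmweber.choice_data import PerformanceRecord
from nmweber.exceptions import ComparisonError, DomainError, FitError
from nmweber.fitting import (
    AIC_PERFECT_FIT,
    FitResult,
    PriorSpec,
    compare_nested,
    fit_bayes,
    fit_nls,
    model_aic,
    model_aic_from_rss,
    paired_param_test,
)
from nmweber.psychometric import PsychometricParams, predict_performance
from nmweber.synthetic_data import SimulationScenario, default_conditions, simulate_performance

CONDITIONS = default_conditions(1)


def noise_free_records(params, n=10**9):
    """Records whose proportions equal the model prediction to ~1e-9."""
    out = []
    for c in CONDITIONS:
        p = predict_performance(c.x, c.a, params)
        out.append(PerformanceRecord(x=c.x, a=c.a, n_high=round(p * n), n_total=n))
    return out


class TestFitNls:
    def test_noise_free_recovery_all_parameters(self):
        truth = PsychometricParams(m=0.2, s=4.0, lapse=0.1, beta=2.0, scale=10.0)
        fit = fit_nls(noise_free_records(truth), beta_mode="free", scale=10.0)
        assert fit.converged
        assert fit.params.m == pytest.approx(truth.m, abs=1e-4)
        assert fit.params.s == pytest.approx(truth.s, abs=1e-4)
        assert fit.params.lapse == pytest.approx(truth.lapse, abs=1e-4)
        assert fit.params.beta == pytest.approx(truth.beta, abs=1e-4)

    def test_deterministic_given_inputs(self, simulated_records):
        a = fit_nls(simulated_records, beta_mode="free")
        b = fit_nls(simulated_records, beta_mode="free")
        assert a.params == b.params and a.rss == b.rss

    def test_free_fit_never_worse_than_fixed(self, simulated_records):
        free = fit_nls(simulated_records, beta_mode="free")
        fixed = fit_nls(simulated_records, beta_mode=1.0)
        assert free.rss <= fixed.rss + 1e-8
        assert (free.n_params, fixed.n_params) == (4, 3)

    def test_beta_ci_ordering_and_coverage_shape(self, simulated_records):
        fit = fit_nls(simulated_records, beta_mode="free")
        lo, hi = fit.beta_ci
        assert lo <= fit.params.beta <= hi

    def test_too_few_records_rejected(self):
        recs = noise_free_records(PsychometricParams(m=0.2, s=4.0))[:3]
        with pytest.raises(FitError, match="at least"):
            fit_nls(recs, beta_mode=1.0)

    def test_degenerate_design_rejected(self):
        recs = [
            PerformanceRecord(x=25.0, a=20.0, n_high=60 + k, n_total=100)
            for k in range(6)
        ]
        with pytest.raises(FitError, match="degenerate"):
            fit_nls(recs, beta_mode=1.0)

    def test_binomial_likelihood_agrees_on_clean_data(self, simulated_records):
        ls = fit_nls(simulated_records, beta_mode=1.0)
        ml = fit_nls(simulated_records, beta_mode=1.0, likelihood="binomial")
        assert ml.params.m == pytest.approx(ls.params.m, rel=0.15)
        assert ml.params.lapse == pytest.approx(ls.params.lapse, abs=0.05)

    def test_zero_substitute_reproduces_epsilon_intensity(self):
        truth = PsychometricParams(m=0.25, s=3.0, lapse=0.1)
        recs = noise_free_records(truth)
        a = fit_nls(recs, beta_mode=1.0)
        b = fit_nls(recs, beta_mode=1.0, zero_substitute=1e-6)
        # epsilon substitution is numerically immaterial but must not break the fit
        assert b.params.m == pytest.approx(a.params.m, rel=1e-3)


class TestAic:
    def test_nested_penalty_is_exactly_two_at_equal_rss(self):
        assert (
            model_aic_from_rss(0.02, 15, 3) - model_aic_from_rss(0.02, 15, 4)
            == pytest.approx(-2.0, abs=1e-12)
        )

    def test_hand_computed_formula(self):
        rss, n, k = 0.01, 15, 4
        expected = n * math.log(2 * math.pi * rss / n) + n + 2 * (k + 1)
        assert model_aic_from_rss(rss, n, k) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_rss(self):
        aics = [model_aic_from_rss(r, 15, 4) for r in (0.001, 0.01, 0.1, 1.0)]
        assert aics == sorted(aics)

    def test_zero_rss_sentinel(self):
        assert model_aic_from_rss(0.0, 15, 4) == AIC_PERFECT_FIT

    def test_model_aic_matches_fit_field(self, simulated_records):
        fit = fit_nls(simulated_records, beta_mode=1.0)
        assert model_aic(fit) == pytest.approx(fit.aic, abs=1e-12)


def _result(rss, n_params, key=("k",)):
    params = PsychometricParams(m=0.2, s=3.0, lapse=0.1, beta=1.5 if n_params == 4 else 1.0)
    return FitResult(
        params=params,
        beta_mode="free" if n_params == 4 else "fixed(1)",
        rss=rss,
        n_points=15,
        n_params=n_params,
        aic=model_aic_from_rss(rss, 15, n_params),
        beta_ci=(1.0, 2.0) if n_params == 4 else None,
        converged=True,
        start_used=(0.2, 3.0, 0.1, 1.0),
        data_key=key,
    )


class TestCompareNested:
    def test_equal_rss_gives_null_comparison(self):
        cmp_ = compare_nested(_result(0.02, 4), _result(0.02, 3))
        assert cmp_.f_stat == 0.0
        assert cmp_.p_value == 1.0
        assert cmp_.delta_aic == pytest.approx(-2.0, abs=1e-12)
        assert (cmp_.df1, cmp_.df2) == (1, 11)

    def test_p_value_against_incomplete_beta(self, simulated_records):
        free = fit_nls(simulated_records, beta_mode="free")
        fixed = fit_nls(simulated_records, beta_mode=1.0)
        cmp_ = compare_nested(free, fixed)
        d2 = cmp_.df2
        # F survival via the regularised incomplete beta function
        expected = special.betainc(d2 / 2.0, 0.5, d2 / (d2 + cmp_.f_stat))
        assert cmp_.p_value == pytest.approx(expected, abs=1e-10)

    def test_different_data_rejected(self):
        with pytest.raises(ComparisonError, match="same records"):
            compare_nested(_result(0.02, 4, key=("a",)), _result(0.02, 3, key=("b",)))

    def test_non_nested_rss_rejected(self):
        with pytest.raises(ComparisonError, match="nested"):
            compare_nested(_result(0.05, 4), _result(0.02, 3))


class TestFitBayes:
    def test_zero_data_recovers_lapse_prior_mean(self):
        summary = fit_bayes([], seed=5)
        prior_mean = 2.0 / 12.0
        mc_se = summary.sd["lapse"] / math.sqrt(summary.ess["lapse"])
        assert abs(summary.mean["lapse"] - prior_mean) < 3 * mc_se

    def test_recovery_within_three_posterior_sds(self, weber_truth):
        scenario = SimulationScenario(params=weber_truth, seed=42)
        records = simulate_performance(scenario)
        post = fit_bayes(records, seed=42)
        for name, true_val in (("m", weber_truth.m), ("s", weber_truth.s),
                               ("lapse", weber_truth.lapse)):
            assert abs(post.mean[name] - true_val) < 3 * post.sd[name], name

    def test_seeded_determinism(self, simulated_records):
        a = fit_bayes(simulated_records, seed=7, n_samples=500, n_burn=100)
        b = fit_bayes(simulated_records, seed=7, n_samples=500, n_burn=100)
        assert a.mean == b.mean and a.quantiles == b.quantiles
        c = fit_bayes(simulated_records, seed=8, n_samples=500, n_burn=100)
        assert a.mean != c.mean

    def test_quantiles_non_decreasing(self, simulated_records):
        post = fit_bayes(simulated_records, seed=7, n_samples=500, n_burn=100)
        for qs in post.quantiles.values():
            vals = [qs[q] for q in sorted(qs)]
            assert vals == sorted(vals)

    def test_agrees_with_least_squares_when_well_identified(self, weber_truth):
        records = simulate_performance(SimulationScenario(params=weber_truth, seed=9))
        post = fit_bayes(records, seed=9)
        nls = fit_nls(records, beta_mode=1.0)
        assert abs(post.mean["m"] - nls.params.m) < 2 * post.sd["m"]
        assert abs(post.mean["s"] - nls.params.s) < 2 * post.sd["s"]
        assert abs(post.mean["lapse"] - nls.params.lapse) < 2 * post.sd["lapse"]

    def test_raw_scale_slope_prior_moment_match(self):
        spec = PriorSpec(slope_loc=2.0, slope_scale=1.0, slope_prior_on="raw")
        mu, sigma = spec.slope_log_params()
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(2.0, rel=1e-12)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert math.sqrt(var) == pytest.approx(1.0, rel=1e-12)


class TestPairedTest:
    def test_identical_vectors_null(self):
        out = paired_param_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out == {"t": 0.0, "df": 2.0, "p": 1.0}

    def test_matches_hand_formula(self):
        low = [3.6, 4.1, 2.9, 3.3, 4.0, 3.8]
        high = [2.1, 2.5, 1.8, 2.6, 2.2, 2.0]
        d = np.array(low) - np.array(high)
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        out = paired_param_test(low, high)
        assert out["t"] == pytest.approx(t_hand, rel=1e-12)
        assert out["df"] == 5

    def test_validates_inputs(self):
        with pytest.raises(DomainError, match="mismatch"):
            paired_param_test([1.0, 2.0], [1.0])
        with pytest.raises(DomainError, match="two"):
            paired_param_test([1.0], [2.0])
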