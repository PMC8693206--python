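"""Count-model fitting: design construction, likelihoods, recovery, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from hai_sir.design import DesignError, DesignMatrix, build_design
from hai_sir.models import (
    CountModelFit,
    ModelError,
    fit_hurdle_negbin,
    fit_negbin,
    fit_poisson,
    fit_truncated_negbin,
    hurdle_nb_loglik,
    loglik_at,
    nb2_zero_prob,
    overdispersion_check,
    predict_expected,
    univariable_screen,
    _truncated_nb_nll_grad,
)
from hai_sir.synthetic import SyntheticConfig, generate_registry

from conftest import make_records


def _simple_dm(y, exposure, X=None, terms=None):
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
        terms = ["intercept"]
    return DesignMatrix(
        response=np.asarray(y, dtype=np.int64),
        predictors=X,
        offset=np.log(np.asarray(exposure, dtype=float)),
        term_names=terms,
    )


class TestBuildDesign:
    def test_offset_is_log_exposure(self):
        rec = make_records([{"n_hospitalizations": v} for v in (3, 9, 27)])
        dm = build_design(rec, [], "RTI")
        assert np.allclose(dm.offset, np.log([3, 9, 27]))

    def test_categorical_reference_coding(self, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, ["ward_type"], "RTI")
        assert sum(t.startswith("ward_type[") for t in dm.term_names) == 8
        assert dm.reference_levels["ward_type"] == "internal"
        # indicator rows sum to at most 1
        block = dm.predictors[:, 1:]
        assert block.sum(axis=1).max() <= 1

    def test_duplicate_predictor_rejected(self, clean_registry):
        rec, _ = clean_registry
        with pytest.raises(DesignError, match="duplicate"):
            build_design(rec, ["mean_age", "mean_age"], "RTI")

    def test_missing_value_names_field(self, small_registry):
        rec, _ = small_registry
        assert rec["surgery_to_surgery_bed_ratio"].isna().any()
        with pytest.raises(DesignError, match="surgery_to_surgery_bed_ratio"):
            build_design(rec, ["surgery_to_surgery_bed_ratio"], "RTI")

    def test_unknown_predictor_rejected(self, clean_registry):
        rec, _ = clean_registry
        with pytest.raises(DesignError, match="not_a_column"):
            build_design(rec, ["not_a_column"], "RTI")


class TestPoisson:
    def test_intercept_only_closed_form(self):
        dm = _simple_dm([2, 4, 6], [50, 50, 50])
        fit = fit_poisson(dm)
        mu = np.exp(dm.predictors @ fit.beta + dm.offset)
        assert np.allclose(mu, 4.0, atol=1e-6)
        assert np.isclose(fit.beta[0], np.log(4.0) - np.log(50.0), atol=1e-6)

    def test_score_identity(self, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, ["ward_type", "mean_age"], "UTI")
        fit = fit_poisson(dm)
        predicted = predict_expected(fit, dm)
        assert abs(predicted.sum() - dm.response.sum()) < 1e-6 * dm.response.sum()

    def test_parameter_recovery(self, rng):
        n = 5000
        x = rng.normal(size=n)
        exposure = rng.integers(50, 500, size=n).astype(float)
        beta_true = np.array([-3.0, 0.4])
        mu = np.exp(beta_true[0] + beta_true[1] * x) * exposure
        y = rng.poisson(mu)
        dm = _simple_dm(y, exposure, np.column_stack([np.ones(n), x]), ["intercept", "x"])
        fit = fit_poisson(dm)
        assert np.all(np.abs(fit.beta - beta_true) < 3 * fit.se_beta)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        dm = _simple_dm(np.arange(10), np.full(10, 100.0), X, ["intercept", "dup"])
        with pytest.raises(ModelError, match="singular"):
            fit_poisson(dm)

    def test_aic_identity(self, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, ["mean_age"], "SSI")
        fit = fit_poisson(dm)
        assert abs(fit.aic - (2 * fit.n_params - 2 * fit.loglik)) < 1e-9


class TestOverdispersion:
    def test_constant_counts_not_flagged(self):
        dm = _simple_dm(np.full(200, 4), np.full(200, 100.0))
        diag = overdispersion_check(dm, fit_poisson(dm))
        assert diag.variance_response <= diag.mean_response
        assert not diag.overdispersed

    def test_nb_data_flagged(self, rng):
        n = 1000
        mu = 5.0
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu), size=n)  # alpha = 1
        dm = _simple_dm(y, np.full(n, 100.0))
        diag = overdispersion_check(dm, fit_poisson(dm))
        assert diag.overdispersed

    def test_zero_excess_detection(self, small_registry):
        rec, _ = small_registry
        dm = build_design(rec, ["ward_type"], "BSI")
        diag = overdispersion_check(dm, fit_poisson(dm))
        # the generator's hurdle produces far more zeros than Poisson allows
        assert diag.zero_excess
        assert diag.zero_observed <= dm.n


class TestNegbin:
    def test_poisson_truth_alpha_near_zero(self, rng):
        n = 5000
        exposure = rng.integers(50, 500, size=n).astype(float)
        y = rng.poisson(0.05 * exposure)
        dm = _simple_dm(y, exposure)
        fit = fit_negbin(dm)
        assert fit.alpha < 0.05

    def test_nb_truth_alpha_recovery(self, rng):
        n = 5000
        alpha = 0.8
        exposure = rng.integers(50, 500, size=n).astype(float)
        mu = 0.05 * exposure
        y = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
        dm = _simple_dm(y, exposure)
        fit = fit_negbin(dm)
        assert 0.6 <= fit.alpha <= 1.0

    def test_nesting_inequality(self, clean_registry):
        rec, _ = clean_registry
        for itype in ("RTI", "UTI"):
            dm = build_design(rec, ["ward_type", "mean_age"], itype)
            assert fit_negbin(dm).loglik >= fit_poisson(dm).loglik - 1e-8


class TestHurdleLoglik:
    def test_all_zero_certain_hurdle(self):
        dm = _simple_dm(np.zeros(20, dtype=int), np.full(20, 100.0))
        # gamma = -40 makes P(positive) ~ 0, so each zero contributes log(1) = 0
        ll = hurdle_nb_loglik(np.array([0.0]), np.array([-40.0]), 0.5, dm)
        assert abs(ll) < 1e-10

    def test_matches_brute_force_mixture(self, rng):
        """Independent oracle: per-record hurdle pmf via scipy nbinom."""
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        offset = np.log(rng.integers(50, 500, size=n).astype(float))
        beta = np.array([-3.0, 0.3])
        gamma = np.array([0.5, -0.4])
        alpha = 0.7
        mu = np.exp(X @ beta + offset)
        p_pos = special.expit(X @ gamma)
        y = np.where(
            rng.uniform(size=n) < p_pos,
            np.maximum(rng.poisson(mu), 1),
            0,
        )
        dm = DesignMatrix(y.astype(np.int64), X, offset, ["intercept", "x"])
        size = 1.0 / alpha
        brute = 0.0
        for i in rng.permutation(n):  # arbitrary summation order
            p = size / (size + mu[i])
            if y[i] == 0:
                brute += np.log(1.0 - p_pos[i])
            else:
                p0 = stats.nbinom.pmf(0, size, p)
                brute += np.log(p_pos[i]) + np.log(
                    stats.nbinom.pmf(y[i], size, p) / (1.0 - p0)
                )
        ours = hurdle_nb_loglik(beta, gamma, alpha, dm)
        assert abs(ours - brute) < 1e-8

    def test_additive_decomposition(self, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, ["mean_age"], "BSI")
        beta = np.array([-3.5, 0.002])
        gamma = np.array([0.4, 0.001])
        alpha = 0.6
        total = hurdle_nb_loglik(beta, gamma, alpha, dm)
        y = dm.response
        xg = dm.predictors @ gamma
        bernoulli = float(
            np.sum(special.log_expit(xg[y > 0])) + np.sum(special.log_expit(-xg[y == 0]))
        )
        pos = y > 0
        from hai_sir.models import truncated_nb2_logpmf

        mu = np.exp(dm.predictors[pos] @ beta + dm.offset[pos])
        positive_part = float(np.sum(truncated_nb2_logpmf(y[pos], mu, alpha)))
        assert abs(total - (bernoulli + positive_part)) < 1e-9

    def test_nonfinite_parameter_rejected(self, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, [], "RTI")
        with pytest.raises(ModelError):
            hurdle_nb_loglik(np.array([np.nan]), np.array([0.0]), 0.5, dm)


class TestTruncatedNB:
    def test_gradient_matches_numeric(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        offset = np.log(rng.integers(50, 200, size=n).astype(float))
        mu = np.exp(-3.0 + 0.3 * X[:, 1]) * np.exp(offset)
        y = np.maximum(rng.poisson(mu), 1).astype(float)
        params = np.array([-2.8, 0.25, np.log(0.5)])
        _, grad = _truncated_nb_nll_grad(params, y, X, offset)
        numeric = optimize.approx_fprime(
            params, lambda p: _truncated_nb_nll_grad(p, y, X, offset)[0], 1e-6
        )
        assert np.allclose(grad, numeric, rtol=1e-4, atol=1e-3)

    def test_agrees_with_statsmodels_truncated_model(self, clean_registry):
        """Dual-route check: the likelihood agrees with the independently
        implemented statsmodels zero-truncated NB at shared parameters, and
        our optimum is at least as good."""
        import warnings

        from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

        rec, _ = clean_registry
        dm = build_design(rec, ["mean_age"], "UTI")
        pos = dm.response > 0
        y = dm.response[pos]
        X = dm.predictors[pos]
        off = dm.offset[pos]
        beta, alpha, ll, _, ok = fit_truncated_negbin(y.astype(float), X, off)
        assert ok
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_res = TruncatedLFNegativeBinomialP(y, X, offset=off, truncation=0).fit(
                disp=0, maxiter=500
            )
        # likelihood functions agree at the statsmodels solution
        nll_at_sm, _ = _truncated_nb_nll_grad(
            np.append(sm_res.params[:-1], np.log(sm_res.params[-1])), y.astype(float), X, off
        )
        assert abs(-nll_at_sm - sm_res.llf) < 1e-6 * abs(sm_res.llf)
        # and our optimizer found an optimum at least as good
        assert ll >= sm_res.llf - 1e-6


class TestHurdleFit:
    def test_requires_zeros_and_positives(self):
        dm = _simple_dm(np.zeros(20, dtype=int), np.full(20, 100.0))
        with pytest.raises(ModelError, match="poisson/negbin"):
            fit_hurdle_negbin(dm)
        dm2 = _simple_dm(np.arange(1, 21), np.full(20, 100.0))
        with pytest.raises(ModelError, match="poisson/negbin"):
            fit_hurdle_negbin(dm2)

    def test_self_consistency_and_local_optimum(self, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, ["mean_age", "nurse_bed_ratio"], "SSI")
        fit = fit_hurdle_negbin(dm)
        assert fit.converged
        ll = hurdle_nb_loglik(fit.beta, fit.gamma, fit.alpha, dm)
        assert abs(ll - fit.loglik) < 1e-9
        # perturbing any single parameter decreases the log-likelihood
        for i in range(len(fit.beta)):
            for d in (-0.01, 0.01):
                b = fit.beta.copy()
                b[i] += d
                assert hurdle_nb_loglik(b, fit.gamma, fit.alpha, dm) < ll
        for i in range(len(fit.gamma)):
            for d in (-0.01, 0.01):
                g = fit.gamma.copy()
                g[i] += d
                assert hurdle_nb_loglik(fit.beta, g, fit.alpha, dm) < ll
        for d in (-0.01, 0.01):
            assert hurdle_nb_loglik(fit.beta, fit.gamma, fit.alpha * np.exp(d), dm) < ll

    def test_parameter_recovery_within_3se(self):
        cfg = SyntheticConfig(
            n_hospitals=1250, wards_per_hospital=4, seed=31,
            beta={"intercept": -3.8, "mean_age": 0.004, "nurse_bed_ratio": -0.15},
            gamma={"intercept": 0.9, "mean_age": -0.003},
            alpha=0.8, infection_types=("UTI",), missing_surgery_ratio_frac=0.0,
        )
        rec, truth = generate_registry(cfg)
        dm = build_design(rec, ["mean_age", "nurse_bed_ratio"], "UTI")
        fit = fit_hurdle_negbin(dm)
        beta_true = np.array([-3.8, 0.004, -0.15])
        gamma_true = np.array([0.9, -0.003, 0.0])
        assert np.all(np.abs(fit.beta - beta_true) < 3 * fit.se_beta)
        assert np.all(np.abs(fit.gamma - gamma_true) < 3 * fit.se_gamma)
        assert abs(fit.alpha - 0.8) < 3 * fit.se_alpha


class TestPredictExpected:
    def test_offset_pass_through(self):
        fit = CountModelFit(
            family="poisson", beta=np.array([0.0]), term_names=["intercept"],
            loglik=0.0, n_params=1, converged=True,
        )
        dm = _simple_dm([0], [100.0])
        assert np.allclose(predict_expected(fit, dm), 100.0)

    def test_hurdle_degenerate_equals_nb_mean(self):
        """When P(positive) = 1 - NB zero mass, the hurdle mean is the NB mean."""
        mu, alpha, exposure = 7.0, 0.6, 100.0
        p0 = float(nb2_zero_prob(np.array([mu]), alpha)[0])
        gamma0 = special.logit(1.0 - p0)
        fit = CountModelFit(
            family="hurdle_negbin", beta=np.array([np.log(mu / exposure)]),
            term_names=["intercept"], loglik=0.0, n_params=3, converged=True,
            alpha=alpha, gamma=np.array([gamma0]),
        )
        dm = _simple_dm([0], [exposure])
        assert np.allclose(predict_expected(fit, dm), mu, rtol=1e-10)

    def test_monte_carlo_mean(self, rng):
        from hai_sir.synthetic import sample_hurdle_nb_count

        mu, alpha, p_zero = 6.0, 0.8, 0.4
        n = 100_000
        draws = sample_hurdle_nb_count(np.full(n, mu), alpha, p_zero, rng)
        p0 = float(nb2_zero_prob(np.array([mu]), alpha)[0])
        expected = (1 - p_zero) * mu / (1 - p0)
        m2 = (1 - p_zero) * (mu + (1 + alpha) * mu**2) / (1 - p0)
        se = np.sqrt((m2 - expected**2) / n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_term_mismatch_rejected(self, clean_registry):
        rec, _ = clean_registry
        dm_a = build_design(rec, ["mean_age"], "RTI")
        dm_b = build_design(rec, ["avg_los"], "RTI")
        fit = fit_poisson(dm_a)
        with pytest.raises(ModelError, match="terms"):
            predict_expected(fit, dm_b)


class TestOffsetEquivariance:
    @pytest.mark.parametrize("fitter", [fit_poisson, fit_negbin])
    def test_rescaled_exposure_shifts_only_intercept(self, fitter, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, ["mean_age"], "UTI")
        fit1 = fitter(dm)
        c = 7.0
        dm2 = DesignMatrix(
            dm.response, dm.predictors, dm.offset + np.log(c), dm.term_names
        )
        fit2 = fitter(dm2)
        assert abs((fit1.beta[0] - fit2.beta[0]) - np.log(c)) < 1e-5
        assert np.allclose(fit1.beta[1:], fit2.beta[1:], atol=1e-6)


class TestLoglikAt:
    def test_matches_reported_loglik(self, clean_registry):
        rec, _ = clean_registry
        dm = build_design(rec, ["mean_age"], "RTI")
        for fitter in (fit_poisson, fit_negbin, fit_hurdle_negbin):
            fit = fitter(dm)
            assert abs(loglik_at(fit, dm) - fit.loglik) < 1e-6


class TestUnivariableScreen:
    def test_empty_candidates(self, clean_registry):
        rec, _ = clean_registry
        retained, notes = univariable_screen(rec, [], "RTI")
        assert retained == [] and notes == []

    def test_strong_effect_retained(self, clean_registry):
        rec, _ = clean_registry
        # ward type carries large true effects (ICU and burn wards) in the
        # generator, so the screen must keep it
        retained, _ = univariable_screen(rec, ["ward_type"], "RTI")
        assert retained == ["ward_type"]
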