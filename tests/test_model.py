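"""Design assembly and the zero-inflated negative binomial likelihood/fit."""

import warnings

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit

from pneumolag.model import (
    ExposureTerm,
    ModelSpec,
    build_design,
    fit_zinb_dlnm,
    pearson_residuals,
    residual_acf,
    zinb_loglik,
    zinb_loglik_grad,
)


def _simulate_zinb(n, p, q, seed, theta=None, gamma=None, alpha=0.7):
    rng = np.random.default_rng(seed)
    X = np.c_[np.ones(n), rng.normal(size=(n, p - 1))]
    Z = np.c_[np.ones(n), rng.normal(size=(n, q - 1))]
    theta = np.asarray(theta) if theta is not None else rng.normal(0, 0.3, p)
    gamma = np.asarray(gamma) if gamma is not None else np.r_[-0.8, rng.normal(0, 0.3, q - 1)]
    mu = np.exp(X @ theta)
    pi = expit(Z @ gamma)
    y = np.where(
        rng.random(n) < pi,
        0,
        rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu)),
    )
    return X, Z, y.astype(float), theta, gamma, alpha


def brute_force_zinb_loglik(theta, gamma, alpha, X, Z, y):
    """Per-observation mixture likelihood via scipy.stats.nbinom."""
    mu = np.exp(X @ theta)
    pi = expit(Z @ gamma)
    r = 1 / alpha
    total = 0.0
    for i in range(len(y)):
        nb = stats.nbinom.pmf(y[i], r, r / (r + mu[i]))
        total += (
            np.log(pi[i] + (1 - pi[i]) * nb) if y[i] == 0 else np.log((1 - pi[i]) * nb)
        )
    return total


class TestDesign:
    def test_first_usable_row_and_shapes(self, daily_short):
        spec = ModelSpec()
        bundle = build_design(daily_short, spec)
        # max(21-day exposure history, 3-day count history) = 21
        assert bundle.first_valid == 21
        assert len(bundle.y) == len(daily_short) - 21
        assert bundle.count_X.shape[0] == bundle.zero_X.shape[0] == len(bundle.y)

    def test_column_count_matches_term_dimensions(self, daily_short):
        spec = ModelSpec(trend_df=4)
        bundle = build_design(daily_short, spec)
        # intercept + 2 lagged crossbases (4 exposure x 4 lag) + unlagged
        # DTR (4) + 6 DOW + 2 Fourier + 4 trend
        expected = 1 + 2 * (4 * 4) + 4 + 6 + 2 + 4
        assert bundle.count_X.shape[1] == expected
        assert len(bundle.count_names) == expected
        # zero: intercept + 6 DOW + 3 previous-day counts + 2 Fourier
        assert bundle.zero_X.shape[1] == 1 + 6 + 3 + 2

    def test_fourier_columns_unit_circle(self, daily_short):
        bundle = build_design(daily_short, ModelSpec())
        j = bundle.count_names.index("fourier_sin1")
        k = bundle.count_names.index("fourier_cos1")
        s, c = bundle.count_X[:, j], bundle.count_X[:, k]
        assert np.allclose(s**2 + c**2, 1.0, atol=1e-12)

    def test_previous_count_columns_are_lagged_response(self, daily_short):
        bundle = build_design(daily_short, ModelSpec())
        y_full = daily_short["count"].to_numpy(dtype=float)
        j = bundle.zero_names.index("prev_count_1")
        assert np.array_equal(bundle.zero_X[:, j], y_full[20:-1])
        j3 = bundle.zero_names.index("prev_count_3")
        assert np.array_equal(bundle.zero_X[:, j3], y_full[18:-3])

    def test_too_short_series_rejected(self, daily_short):
        with pytest.raises(ValueError):
            build_design(daily_short.iloc[:20], ModelSpec())


class TestLikelihood:
    def test_matches_per_observation_oracle(self):
        X, Z, y, theta, gamma, alpha = _simulate_zinb(50, 3, 2, seed=101)
        params = np.r_[theta, gamma, np.log(alpha)]
        assert zinb_loglik(params, X, Z, y) == pytest.approx(
            brute_force_zinb_loglik(theta, gamma, alpha, X, Z, y), abs=1e-10
        )

    def test_pi_zero_reduces_to_negative_binomial(self):
        X, Z, y, theta, _, alpha = _simulate_zinb(60, 3, 2, seed=102)
        params = np.r_[theta, [-40.0, 0.0], np.log(alpha)]
        mu = np.exp(X @ theta)
        r = 1 / alpha
        ll_nb = stats.nbinom.logpmf(y, r, r / (r + mu)).sum()
        assert zinb_loglik(params, X, Z, y) == pytest.approx(ll_nb, abs=1e-8)

    def test_small_dispersion_approaches_poisson(self):
        X, Z, y, theta, _, _ = _simulate_zinb(60, 3, 2, seed=103, alpha=0.01)
        params = np.r_[theta, [-40.0, 0.0], np.log(1e-8)]
        mu = np.exp(X @ theta)
        ll_pois = stats.poisson.logpmf(y, mu).sum()
        assert zinb_loglik(params, X, Z, y) == pytest.approx(ll_pois, abs=1e-4)

    def test_analytic_gradient_matches_numerical(self):
        X, Z, y, theta, gamma, alpha = _simulate_zinb(40, 3, 2, seed=104)
        params = np.r_[theta, gamma, np.log(alpha)]
        err = optimize.check_grad(
            lambda t: zinb_loglik(t, X, Z, y),
            lambda t: zinb_loglik_grad(t, X, Z, y),
            params,
        )
        assert err < 1e-4


@pytest.fixture(scope="module")
def fitted():
    X, Z, y, theta, gamma, alpha = _simulate_zinb(
        800, 4, 2, seed=105, theta=[0.4, -0.3, 0.2, 0.1], gamma=[-0.9, 0.4]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_zinb_dlnm(X, Z, y)
    return fit, X, Z, y, theta, alpha


class TestFit:
    def test_first_order_condition_at_optimum(self, fitted):
        fit, X, Z, y, *_ = fitted
        params = np.r_[fit.count_params, fit.zero_params, np.log(fit.alpha)]
        grad = zinb_loglik_grad(params, X, Z, y)
        assert np.max(np.abs(grad)) / len(y) < 1e-4
        assert fit.converged

    def test_improves_on_nb_only_start(self, fitted):
        """Fitted mixture log-likelihood must beat the plain NB model at
        the initialization values (monotone improvement)."""
        fit, X, Z, y, *_ = fitted
        import statsmodels.api as sm

        theta0 = sm.GLM(y, X, family=sm.families.Poisson()).fit().params
        start_nb = np.r_[theta0, [-40.0] + [0.0] * (Z.shape[1] - 1), np.log(0.5)]
        assert fit.loglik >= zinb_loglik(start_nb, X, Z, y)

    def test_recovers_generating_parameters(self, fitted):
        fit, X, Z, y, theta, alpha = fitted
        se = np.sqrt(np.diag(fit.covariance))[: len(theta)]
        assert np.all(np.abs(fit.count_params - theta) < 4 * se)
        assert 0.3 < fit.alpha / alpha < 3.0

    def test_covariance_symmetric_psd(self, fitted):
        fit, *_ = fitted
        assert np.allclose(fit.covariance, fit.covariance.T)
        assert np.linalg.eigvalsh(fit.covariance).min() >= -1e-12

    def test_matches_statsmodels_zinb_loglik(self, fitted):
        """Independent cross-check: statsmodels' zero-inflated NB gives
        the same log-likelihood at our fitted parameters."""
        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        fit, X, Z, y, *_ = fitted
        sm_model = ZeroInflatedNegativeBinomialP(y, X, exog_infl=Z, p=2)
        sm_params = np.r_[fit.zero_params, fit.count_params, fit.alpha]
        assert sm_model.loglike(sm_params) == pytest.approx(fit.loglik, rel=1e-10)

    def test_column_rescaling_leaves_predictions_invariant(self):
        X, Z, y, *_ = _simulate_zinb(400, 3, 2, seed=106)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_zinb_dlnm(X, Z, y)
            X2 = X.copy()
            X2[:, 1] *= 10.0
            f2 = fit_zinb_dlnm(X2, Z, y)
        eta1 = X @ f1.count_params
        eta2 = X2 @ f2.count_params
        assert np.max(np.abs(eta1 - eta2)) < 1e-6

    def test_all_zero_response_rejected(self):
        X = np.ones((30, 1))
        Z = np.ones((30, 1))
        with pytest.raises(ValueError):
            fit_zinb_dlnm(X, Z, np.zeros(30))

    def test_rank_deficiency_reported_with_column_name(self):
        rng = np.random.default_rng(107)
        x1 = rng.normal(size=50)
        X = np.c_[np.ones(50), x1, 2 * x1]
        Z = np.ones((50, 1))
        y = rng.poisson(1.0, 50).astype(float)
        with pytest.raises(ValueError, match="dup_col"):
            fit_zinb_dlnm(X, Z, y, count_names=["intercept", "x", "dup_col"])

    def test_residuals_and_acf_computable(self, daily_short):
        spec = ModelSpec(trend_df=3)
        bundle = build_design(daily_short, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pneumolag.model import fit_from_bundle

            fit = fit_from_bundle(bundle)
        resid = pearson_residuals(fit, bundle)
        assert np.all(np.isfinite(resid))
        acf = residual_acf(resid, nlags=20)
        assert acf.shape == (21,) and acf[0] == pytest.approx(1.0)
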