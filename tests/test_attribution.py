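"""Backward attributable fractions: closed forms, decompositions, scenarios, MC CIs."""

import copy

import numpy as np
import pytest

from pneumolag.attribution import backward_af, mc_ci, scenario_af
from pneumolag.basis import SplineSpec, crossbasis, lag_basis_matrix, ns_basis
from pneumolag.model import FittedZINB
from pneumolag.prediction import _term_indices

CENTER = 21.0


def _toy_fit(cb, theta_cb, cov_scale=0.0):
    """Hand-built fitted object holding only an intercept and one term."""
    p = 1 + len(theta_cb)
    cov = np.zeros((p + 1 + 1, p + 1 + 1))
    if cov_scale:
        cov[1 : 1 + len(theta_cb), 1 : 1 + len(theta_cb)] = cov_scale * np.eye(
            len(theta_cb)
        )
    return FittedZINB(
        count_params=np.r_[0.1, theta_cb],
        count_names=["intercept"] + cb.column_names(),
        zero_params=np.array([-1.0]),
        zero_names=["intercept"],
        alpha=0.5,
        covariance=cov,
        loglik=0.0,
        converged=True,
        n_used=100,
        grad_norm=0.0,
        term_slices={cb.source_name: slice(1, 1 + len(theta_cb))},
    )


@pytest.fixture(scope="module")
def unlagged_setup():
    """Unlagged exposure whose fitted curve is exactly linear: 0.05*(x-21).

    Natural splines contain linear functions, so the coefficient vector
    reproducing the line exists exactly (least squares on a dense grid).
    """
    espec = SplineSpec((15.0, 21.0, 27.0), (8.0, 35.0))
    grid = np.linspace(8.0, 35.0, 300)
    target = 0.05 * (grid - CENTER)
    b = ns_basis(grid, espec) - ns_basis([CENTER], espec)
    theta, *_ = np.linalg.lstsq(b, target, rcond=None)
    rng = np.random.default_rng(71)
    x = rng.uniform(10, 32, 120)
    cb = crossbasis(x, 0, espec, None, source_name="dtr_like")
    counts = rng.poisson(1.3, 120).astype(float)
    fit = _toy_fit(cb, theta)
    return fit, cb, x, counts, theta


class TestClosedForms:
    def test_null_coefficients_give_zero_af(self, null_fit):
        fit0, cb, x, y = null_fit
        res = backward_af(fit0, cb, x, y[:], CENTER)
        assert res.total_af == 0.0
        assert res.attributable_number == 0.0

    def test_exposures_at_center_give_zero_af(self, compact_fit):
        fit, cb, x, y, _ = compact_fit
        const = np.full_like(x, CENTER)
        res = backward_af(fit, cb, const, y, CENTER)
        assert res.total_af == pytest.approx(0.0, abs=1e-14)

    def test_single_day_closed_form(self):
        """One admission after a constant-exposure history: AF = 1 - e^{-s}
        with s the hand-computed cumulative log-RR of that exposure."""
        espec = SplineSpec((18.0, 24.0), (10.0, 32.0))
        from pneumolag.basis import lag_spline_spec

        lspec = lag_spline_spec(5, 1)
        x0 = 28.0
        x = np.full(30, x0)
        cb = crossbasis(x, 5, espec, lspec, source_name="t")
        rng = np.random.default_rng(72)
        theta = rng.normal(0, 0.05, cb.matrix.shape[1])
        counts = np.zeros(25)
        counts[-1] = 1.0
        # hand-computed eta sum: all lagged exposures equal x0
        bx = (ns_basis([x0], espec) - ns_basis([CENTER], espec))[0]
        bl = lag_basis_matrix(lspec, 5)
        s = sum(np.kron(bx, bl[l]) @ theta for l in range(6))
        fit = _toy_fit(cb, theta)
        res = backward_af(fit, cb, x, counts, CENTER)
        assert res.total_af == pytest.approx(1 - np.exp(-s), abs=1e-12)

    def test_protective_exposure_gives_negative_af(self, unlagged_setup):
        fit, cb, x, counts, theta = unlagged_setup
        cold = np.full_like(x, 15.0)  # below center, linear slope +0.05
        res = backward_af(fit, cb, cold, counts, CENTER)
        assert res.total_af < 0
        assert res.total_af == pytest.approx(1 - np.exp(0.05 * 6.0), abs=1e-9)

    def test_loglinear_shift_closed_form(self, unlagged_setup):
        """Unlagged linear effect beta*(x-c): per-day AF under shift d is
        1 - e^{-beta*(x_t + d - c)}, aggregated with count weights."""
        fit, cb, x, counts, theta = unlagged_setup
        delta = 2.0
        res = scenario_af(fit, cb, x, counts, CENTER, shift=delta)
        expected_daily = 1 - np.exp(-0.05 * (x + delta - CENTER))
        expected = (expected_daily * counts).sum() / counts.sum()
        assert res.total_af == pytest.approx(expected, abs=1e-9)


class TestDecomposition:
    def test_partitioning_subranges_sum_to_total(self, compact_fit):
        """Blocks of off-center exposure separated by >= 22 center days:
        every day's lag window then draws contributions from one side
        only, and the low/high AFs must sum to the total exactly."""
        fit, cb, _, _, _ = compact_fit
        x = np.full(200, CENTER)
        x[30:55] = 13.0   # a cold block
        x[100:125] = 29.0  # a hot block
        rng = np.random.default_rng(73)
        counts = rng.poisson(1.3, 200 - cb.max_lag).astype(float)
        subr = {"low": (-np.inf, CENTER), "high": (CENTER, np.inf)}
        # the center itself contributes eta = 0, so including it in both
        # subranges is harmless; exclude it from one side regardless
        subr = {"low": (-np.inf, 20.999), "high": (21.001, np.inf)}
        res = backward_af(fit, cb, x, counts, CENTER, subranges=subr)
        assert res.subrange_af["low"] + res.subrange_af["high"] == pytest.approx(
            res.total_af, abs=1e-10
        )

    def test_af_invariant_to_count_scaling(self, compact_fit):
        fit, cb, x, y, _ = compact_fit
        res1 = backward_af(fit, cb, x, y, CENTER)
        res2 = backward_af(fit, cb, x, 7.0 * y, CENTER)
        assert res1.total_af == pytest.approx(res2.total_af, rel=1e-12)

    def test_constant_exposure_backward_equals_single_day(self, compact_fit):
        """With exposure never varying there is no lag mixing: every day's
        backward AF equals the single-day cumulative AF."""
        fit, cb, _, y, _ = compact_fit
        x0 = 26.0
        x = np.full(100, x0)
        counts = np.ones(100 - cb.max_lag)
        res = backward_af(fit, cb, x, counts, CENTER)
        from pneumolag.prediction import predict_rr

        cp = predict_rr(fit, cb, exposure_grid=[x0], center=CENTER)
        expected = 1 - 1 / cp.cum_rr[0]
        assert res.total_af == pytest.approx(expected, abs=1e-12)


class TestScenarios:
    def test_zero_shift_identical_to_unshifted(self, compact_fit):
        fit, cb, x, y, _ = compact_fit
        a = backward_af(fit, cb, x, y, CENTER)
        b = scenario_af(fit, cb, x, y, CENTER, shift=0.0)
        assert a.total_af == b.total_af  # bit-identical
        assert a.attributable_number == b.attributable_number

    def test_null_coefficients_any_shift_zero(self, null_fit):
        fit0, cb, x, y = null_fit
        res = scenario_af(fit0, cb, x, y, CENTER, shift=5.0)
        assert res.total_af == 0.0

    def test_history_length_mismatch_rejected(self, compact_fit):
        fit, cb, x, y, _ = compact_fit
        with pytest.raises(ValueError):
            backward_af(fit, cb, x[:-1], y, CENTER)


class TestMonteCarloCI:
    def test_zero_covariance_collapses_to_point(self, compact_fit):
        fit, cb, x, y, _ = compact_fit
        fit0 = copy.deepcopy(fit)
        fit0.covariance = np.zeros_like(fit0.covariance)
        res = mc_ci(fit0, cb, x, y, CENTER, n_mc=50, seed=4)
        assert res.ci_low == pytest.approx(res.total_af, abs=1e-14)
        assert res.ci_high == pytest.approx(res.total_af, abs=1e-14)

    def test_same_seed_reproduces_interval_exactly(self, compact_fit):
        fit, cb, x, y, _ = compact_fit
        a = mc_ci(fit, cb, x, y, CENTER, n_mc=100, seed=9)
        b = mc_ci(fit, cb, x, y, CENTER, n_mc=100, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_n_mc_too_small_rejected(self, compact_fit):
        fit, cb, x, y, _ = compact_fit
        with pytest.raises(ValueError):
            mc_ci(fit, cb, x, y, CENTER, n_mc=1, seed=1)

    def test_scalar_toy_matches_analytic_quantiles(self):
        """Constant exposure, one effective coefficient: s ~ N(m, v) so the
        AF percentiles are the monotone image 1 - e^{-q(s)}."""
        espec = SplineSpec((20.0,), (10.0, 30.0))
        x0 = 27.0
        x = np.full(40, x0)
        cb = crossbasis(x, 0, espec, None, source_name="t")
        theta = np.array([0.3, -0.1])
        var = 0.02
        p = len(theta)
        fit = _toy_fit(cb, theta, cov_scale=var)
        counts = np.ones(40)
        res = mc_ci(fit, cb, x, counts, CENTER, n_mc=4000, seed=11)
        bx = (ns_basis([x0], espec) - ns_basis([CENTER], espec))[0]
        m = bx @ theta
        sd = np.sqrt(var * (bx @ bx))
        lo_true = 1 - np.exp(-(m - 1.96 * sd))
        hi_true = 1 - np.exp(-(m + 1.96 * sd))
        assert res.ci_low == pytest.approx(lo_true, abs=0.02)
        assert res.ci_high == pytest.approx(hi_true, abs=0.02)
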