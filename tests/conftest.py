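"""Shared fixtures: small synthetic studies and a compact fitted model.

Everything is generated programmatically with fixed seeds; the compact
single-exposure fit is session-scoped because several prediction and
attribution tests interrogate the same fitted object.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.special import expit

from pneumolag.basis import SplineSpec, crossbasis, lag_spline_spec
from pneumolag.model import fit_zinb_dlnm
from pneumolag.synthetic import (
    default_truth,
    simulate_admissions,
    simulate_meteorology,
)


@pytest.fixture(scope="session")
def met_short():
    return simulate_meteorology(400, seed=11)


@pytest.fixture(scope="session")
def daily_short(met_short):
    return simulate_admissions(met_short, default_truth(), seed=12)


@pytest.fixture(scope="session")
def compact_fit():
    """A small single-exposure ZINB fit with known generating parameters.

    Returns (fit, cb, exposure_series, counts, theta_true): a crossbasis
    for mean temperature over a 21-day lag with one internal knot in
    each dimension, fitted to counts simulated from known coefficients.
    """
    espec = SplineSpec((21.0,), (8.0, 35.0))
    lspec = lag_spline_spec(21, 1)
    met = simulate_meteorology(1021, seed=21)
    x = met["mean_temp"].to_numpy()
    cb = crossbasis(x, 21, espec, lspec, source_name="mean_temp")
    theta_cb = np.array([-0.02, 0.015, -0.03, 0.01, -0.015, 0.02])
    theta_true = np.concatenate([[0.3], theta_cb])
    gamma_true = np.array([-1.2])
    alpha_true = 0.5
    X = np.c_[np.ones(len(x)), cb.matrix][21:]
    Z = np.ones((len(x) - 21, 1))
    rng = np.random.default_rng(22)
    mu = np.exp(X @ theta_true)
    pi = expit(Z @ gamma_true).ravel()
    y = np.where(
        rng.random(len(mu)) < pi,
        0,
        rng.negative_binomial(1 / alpha_true, 1 / (1 + alpha_true * mu)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_zinb_dlnm(
            X, Z, y,
            count_names=["intercept"] + cb.column_names(),
            zero_names=["intercept"],
            term_slices={"mean_temp": slice(1, 1 + cb.matrix.shape[1])},
        )
    return fit, cb, x, y, theta_true


@pytest.fixture()
def null_fit(compact_fit):
    """The compact fit with all crossbasis coefficients and covariance zeroed."""
    import copy

    fit, cb, x, y, _ = compact_fit
    fit0 = copy.deepcopy(fit)
    fit0.count_params = np.zeros_like(fit0.count_params)
    fit0.covariance = np.zeros_like(fit0.covariance)
    return fit0, cb, x, y
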