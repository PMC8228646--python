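"""Design assembly and maximum-likelihood fitting of the zero-inflated
negative binomial (ZINB) distributed-lag model.

The rate (count) component models the log daily admission rate with
exposure-lag crossbases for mean temperature and relative humidity
(21-day lag window), an unlagged natural-spline term for daily
temperature range, day-of-week indicators (Sunday reference), a Fourier
pair with a 6-month period capturing periodic seasonality, and a
long-term trend spline over the day index.  The zero-inflation
(binomial) component models the extra probability of a zero-admission
day with day-of-week indicators, linear terms for the admission counts
of the preceding three days (an infectious-disease / autocorrelation
device), and optionally the same Fourier pair.

The likelihood uses the NB2 parameterization (variance = mu + alpha*mu^2)
mixed with a logistic point mass at zero:

    y_t = 0:  log[ pi_t + (1 - pi_t) * NB(0; mu_t, alpha) ]
    y_t > 0:  log(1 - pi_t) + log NB(y_t; mu_t, alpha)

with mu_t = exp(x_t' theta), pi_t = logistic(z_t' gamma).  The
dispersion is fitted on the log scale; the optimizer is BFGS with the
analytic gradient, and the covariance is the inverse observed
information at the optimum (differentiated from the analytic gradient).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .basis import CrossBasis, SplineSpec, crossbasis, lag_spline_spec, ns_basis

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureTerm",
    "ModelSpec",
    "DesignBundle",
    "FittedZINB",
    "build_design",
    "zinb_loglik",
    "zinb_loglik_grad",
    "fit_zinb_dlnm",
    "pearson_residuals",
    "residual_acf",
    "coefficient_table",
]

#: Length in days of a 6-month Fourier period (365.25 / 2).
HALF_YEAR_DAYS = 182.625

_DOW_NAMES = {1: "mon", 2: "tue", 3: "wed", 4: "thu", 5: "fri", 6: "sat", 7: "sun"}


@dataclass
class ExposureTerm:
    """One meteorological exposure entering the rate component.

    ``max_lag=0`` gives the unlagged (same-day) special case used for
    daily temperature range.  If ``exposure_spec`` is None, knots are
    placed at equally spaced percentiles of the observed series.
    """

    name: str
    center: float
    max_lag: int = 21
    n_exposure_knots: int = 3
    n_lag_knots: int = 2
    exposure_spec: SplineSpec | None = None
    lag_spec: SplineSpec | None = None

    def resolve_specs(self, series) -> tuple[SplineSpec, SplineSpec | None]:
        espec = self.exposure_spec or SplineSpec.from_data(series, self.n_exposure_knots)
        lspec = self.lag_spec if self.max_lag == 0 or self.lag_spec is not None else lag_spline_spec(
            self.max_lag, self.n_lag_knots
        )
        if self.max_lag == 0:
            lspec = None
        return espec, lspec


def default_exposure_terms() -> list[ExposureTerm]:
    """Mean temperature and RH over a 21-day lag window; DTR unlagged.

    Centers are the study medians (21 degC mean temperature, 67 % RH)
    and the lowest observed DTR (1.3 degC), the references at which the
    predicted rate ratio equals 1.
    """
    return [
        ExposureTerm("mean_temp", center=21.0, max_lag=21),
        ExposureTerm("rh", center=67.0, max_lag=21),
        ExposureTerm("dtr", center=1.3, max_lag=0),
    ]


@dataclass
class ModelSpec:
    """Structure of the two-component ZINB distributed-lag model."""

    exposures: list[ExposureTerm] = field(default_factory=default_exposure_terms)
    n_fourier_pairs: int = 1
    fourier_period: float = HALF_YEAR_DAYS
    fourier_in_zero: bool = True
    trend_df: int = 5
    zero_prev_days: int = 3

    @property
    def centers(self) -> dict[str, float]:
        return {t.name: t.center for t in self.exposures}


@dataclass
class DesignBundle:
    """Design matrices plus the metadata linking columns back to terms."""

    count_X: np.ndarray
    count_names: list[str]
    zero_X: np.ndarray
    zero_names: list[str]
    y: np.ndarray
    crossbases: dict[str, CrossBasis]
    term_slices: dict[str, slice]
    index: pd.DatetimeIndex
    first_valid: int


def _dow_dummies(dow: np.ndarray) -> tuple[np.ndarray, list[str]]:
    # Sunday (7) is the reference category
    levels = [1, 2, 3, 4, 5, 6]
    cols = np.column_stack([(dow == lv).astype(float) for lv in levels])
    names = [f"dow_{_DOW_NAMES[lv]}" for lv in levels]
    return cols, names


def build_design(daily: pd.DataFrame, spec: ModelSpec) -> DesignBundle:
    """Assemble count- and zero-component designs from a daily series.

    Usable rows are those with a complete lag history for every
    crossbasis and a complete ``zero_prev_days`` count history; earlier
    rows are dropped from both designs (not zero-padded).
    """
    n = len(daily)
    max_lag = max([t.max_lag for t in spec.exposures], default=0)
    first = max(max_lag, spec.zero_prev_days)
    if n <= first:
        raise ValueError(
            f"series of length {n} too short for lag history {first}"
        )
    y_full = daily["count"].to_numpy(dtype=float)
    dow = daily["dow"].to_numpy() if "dow" in daily else daily.index.dayofweek + 1

    count_cols: list[np.ndarray] = [np.ones(n)]
    count_names: list[str] = ["intercept"]
    crossbases: dict[str, CrossBasis] = {}
    term_slices: dict[str, slice] = {}
    for term in spec.exposures:
        series = daily[term.name].to_numpy(dtype=float)
        espec, lspec = term.resolve_specs(series)
        cb = crossbasis(series, term.max_lag, espec, lspec, source_name=term.name)
        crossbases[term.name] = cb
        start = sum(c.shape[1] if c.ndim == 2 else 1 for c in count_cols)
        term_slices[term.name] = slice(start, start + cb.matrix.shape[1])
        count_cols.append(cb.matrix)
        count_names.extend(cb.column_names())

    dow_cols, dow_names = _dow_dummies(np.asarray(dow))
    count_cols.append(dow_cols)
    count_names.extend(dow_names)

    t_idx = np.arange(n, dtype=float)
    fourier_cols: list[np.ndarray] = []
    fourier_names: list[str] = []
    for k in range(1, spec.n_fourier_pairs + 1):
        w = 2 * np.pi * k * t_idx / spec.fourier_period
        fourier_cols.extend([np.sin(w), np.cos(w)])
        fourier_names.extend([f"fourier_sin{k}", f"fourier_cos{k}"])
    if fourier_cols:
        count_cols.append(np.column_stack(fourier_cols))
        count_names.extend(fourier_names)

    if spec.trend_df >= 2:
        trend_spec = SplineSpec.from_data(t_idx, n_knots=spec.trend_df - 1)
        trend = ns_basis(t_idx, trend_spec)
        count_cols.append(trend)
        count_names.extend([f"trend{j + 1}" for j in range(trend.shape[1])])
    elif spec.trend_df == 1:
        count_cols.append((t_idx / n).reshape(-1, 1))
        count_names.append("trend1")

    count_X = np.column_stack(count_cols)

    zero_cols = [np.ones(n)]
    zero_names = ["intercept"]
    zero_cols.append(dow_cols)
    zero_names.extend(dow_names)
    for d in range(1, spec.zero_prev_days + 1):
        lagged = np.zeros(n)
        lagged[d:] = y_full[:-d]
        zero_cols.append(lagged.reshape(-1, 1))
        zero_names.append(f"prev_count_{d}")
    if spec.fourier_in_zero and fourier_cols:
        zero_cols.append(np.column_stack(fourier_cols))
        zero_names.extend(fourier_names)
    zero_X = np.column_stack(zero_cols)

    if len(set(count_names)) != len(count_names) or len(set(zero_names)) != len(zero_names):
        raise ValueError("duplicated design column names")

    return DesignBundle(
        count_X=count_X[first:],
        count_names=count_names,
        zero_X=zero_X[first:],
        zero_names=zero_names,
        y=y_full[first:],
        crossbases=crossbases,
        term_slices=term_slices,
        index=daily.index[first:],
        first_valid=first,
    )


# ---------------------------------------------------------------------------
# likelihood


def _unpack(params, p, q):
    params = np.asarray(params, dtype=float)
    return params[:p], params[p : p + q], params[p + q]


def zinb_loglik(params, count_design, zero_design, y) -> float:
    """ZINB log-likelihood at ``params = [theta, gamma, log(alpha)]``.

    NB2 parameterization: variance = mu + alpha * mu^2.  Raises if the
    result is non-finite, naming the first offending observation.
    """
    X = np.asarray(count_design, dtype=float)
    Z = np.asarray(zero_design, dtype=float)
    y = np.asarray(y, dtype=float)
    theta, gamma, tau = _unpack(params, X.shape[1], Z.shape[1])
    alpha = np.exp(tau)
    eta = X @ theta
    zeta = Z @ gamma
    log_pi = -np.logaddexp(0.0, -zeta)
    log_1mpi = -np.logaddexp(0.0, zeta)
    log_denom = np.log1p(alpha * np.exp(eta))
    log_p0 = -log_denom / alpha

    ll = np.empty_like(y)
    is0 = y == 0
    ll[is0] = np.logaddexp(log_pi[is0], log_1mpi[is0] + log_p0[is0])
    pos = ~is0
    yp = y[pos]
    r = 1.0 / alpha
    lognb = (
        special.gammaln(yp + r)
        - special.gammaln(r)
        - special.gammaln(yp + 1)
        - r * log_denom[pos]
        + yp * (tau + eta[pos] - log_denom[pos])
    )
    ll[pos] = log_1mpi[pos] + lognb
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite log-likelihood at row {bad}")
    return float(ll.sum())


def zinb_loglik_grad(params, count_design, zero_design, y) -> np.ndarray:
    """Analytic gradient of :func:`zinb_loglik` in ``[theta, gamma, log(alpha)]``."""
    X = np.asarray(count_design, dtype=float)
    Z = np.asarray(zero_design, dtype=float)
    y = np.asarray(y, dtype=float)
    theta, gamma, tau = _unpack(params, X.shape[1], Z.shape[1])
    alpha = np.exp(tau)
    r = 1.0 / alpha
    eta = X @ theta
    mu = np.exp(eta)
    zeta = Z @ gamma
    log_pi = -np.logaddexp(0.0, -zeta)
    log_1mpi = -np.logaddexp(0.0, zeta)
    one_amu = 1.0 + alpha * mu
    log_p0 = -np.log1p(alpha * mu) / alpha

    u = np.empty_like(y)  # d ll / d eta
    v = np.empty_like(y)  # d ll / d zeta
    w = np.empty_like(y)  # d ll / d tau

    is0 = y == 0
    if is0.any():
        ll0 = np.logaddexp(log_pi[is0], log_1mpi[is0] + log_p0[is0])
        w0 = np.exp(log_1mpi[is0] + log_p0[is0] - ll0)  # (1-pi) P0 / D
        u[is0] = -w0 * mu[is0] / one_amu[is0]
        v[is0] = np.exp(log_pi[is0] + log_1mpi[is0] - ll0) * (-np.expm1(log_p0[is0]))
        w[is0] = w0 * (np.log1p(alpha * mu[is0]) / alpha - mu[is0] / one_amu[is0])
    pos = ~is0
    if pos.any():
        yp = y[pos]
        u[pos] = (yp - mu[pos]) / one_amu[pos]
        v[pos] = -np.exp(log_pi[pos])
        w[pos] = -r * (
            special.digamma(yp + r)
            - special.digamma(r)
            - np.log1p(alpha * mu[pos])
            + 1.0
            - (1.0 + alpha * yp) / one_amu[pos]
        )
    return np.concatenate([X.T @ u, Z.T @ v, [w.sum()]])


@dataclass
class FittedZINB:
    """A fitted ZINB distributed-lag model.

    ``covariance`` is over the free parameters in the order
    ``count coefficients, zero coefficients, log(alpha)``.
    """

    count_params: np.ndarray
    count_names: list[str]
    zero_params: np.ndarray
    zero_names: list[str]
    alpha: float
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    grad_norm: float
    term_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def n_count(self) -> int:
        return len(self.count_params)

    def count_cov(self) -> np.ndarray:
        p = self.n_count
        return self.covariance[:p, :p]

    def term_params(self, name: str) -> np.ndarray:
        return self.count_params[self.term_slices[name]]

    def term_cov(self, name: str) -> np.ndarray:
        s = self.term_slices[name]
        return self.covariance[s, s]

    def param_labels(self) -> list[str]:
        return (
            [f"count:{n}" for n in self.count_names]
            + [f"zero:{n}" for n in self.zero_names]
            + ["log_alpha"]
        )


def _check_rank(X: np.ndarray, names: list[str], label: str) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 10
    bad = [names[j] for j in np.flatnonzero(diag < tol)]
    if bad:
        raise ValueError(f"{label} design is rank deficient; collinear columns: {bad}")


def fit_zinb_dlnm(
    count_design,
    zero_design,
    y,
    count_names: list[str] | None = None,
    zero_names: list[str] | None = None,
    term_slices: dict[str, slice] | None = None,
    maxiter: int = 2000,
    gtol: float = 1e-6,
) -> FittedZINB:
    """Fit the ZINB model by BFGS with the analytic gradient.

    Initialization: Poisson GLM for the count coefficients, zeros for
    the zero component, dispersion 0.5.  The covariance is the inverse
    observed information (numerical Jacobian of the analytic gradient),
    symmetrized.  Non-convergence returns a result with
    ``converged=False`` and a warning rather than raising.
    """
    X = np.asarray(count_design, dtype=float)
    Z = np.asarray(zero_design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    q = Z.shape[1]
    count_names = count_names or [f"x{j}" for j in range(p)]
    zero_names = zero_names or [f"z{j}" for j in range(q)]
    if np.all(y == 0):
        raise ValueError("all-zero response: count model is not identifiable")
    _check_rank(X, count_names, "count")
    _check_rank(Z, zero_names, "zero")

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            theta0 = sm.GLM(y, X, family=sm.families.Poisson()).fit().params
        except Exception:  # fall back to a crude log-linear start
            theta0, *_ = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)
    x0 = np.concatenate([theta0, np.zeros(q), [np.log(0.5)]])

    def nll(params):
        try:
            return -zinb_loglik(params, X, Z, y)
        except FloatingPointError:
            return np.inf

    def ngrad(params):
        return -zinb_loglik_grad(params, X, Z, y)

    with np.errstate(over="ignore"):
        res = optimize.minimize(
            nll, x0, jac=ngrad, method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        grad = zinb_loglik_grad(res.x, X, Z, y)
        grad_scaled = float(np.max(np.abs(grad))) / n
        converged = bool(grad_scaled < 1e-4)
        if not converged:
            # one polishing pass helps when BFGS stalls on curvature
            res2 = optimize.minimize(
                nll, res.x, jac=ngrad, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
            )
            if res2.fun <= res.fun:
                res = res2
            grad = zinb_loglik_grad(res.x, X, Z, y)
            grad_scaled = float(np.max(np.abs(grad))) / n
            converged = bool(grad_scaled < 1e-4)
    if not converged:
        warnings.warn(
            f"ZINB optimizer did not meet the gradient criterion "
            f"(scaled max gradient {grad_scaled:.2e})"
        )

    from statsmodels.tools.numdiff import approx_fprime

    hess = -approx_fprime(res.x, lambda t: zinb_loglik_grad(t, X, Z, y), centered=True)
    hess = (hess + hess.T) / 2
    # Truncated-eigenvalue inverse of the observed information.  When the
    # zero component hits a boundary (a category's inflation probability
    # collapses to 0, coefficients diverging to -inf), the information is
    # singular along those directions; the pseudo-inverse reports zero
    # variance there instead of contaminating the whole covariance.
    evals, evecs = np.linalg.eigh(hess)
    tol = max(float(evals.max()), 1.0) * 1e-9
    inv_evals = np.where(evals > tol, 1.0 / np.where(evals > tol, evals, 1.0), 0.0)
    cov = (evecs * inv_evals) @ evecs.T
    cov = (cov + cov.T) / 2

    theta, gamma, tau = _unpack(res.x, p, q)
    return FittedZINB(
        count_params=theta,
        count_names=list(count_names),
        zero_params=gamma,
        zero_names=list(zero_names),
        alpha=float(np.exp(tau)),
        covariance=cov,
        loglik=float(-res.fun),
        converged=converged,
        n_used=n,
        grad_norm=grad_scaled,
        term_slices=dict(term_slices or {}),
    )


def fit_from_bundle(bundle: DesignBundle, **kwargs) -> FittedZINB:
    """Convenience wrapper: fit directly from a :class:`DesignBundle`."""
    return fit_zinb_dlnm(
        bundle.count_X,
        bundle.zero_X,
        bundle.y,
        count_names=bundle.count_names,
        zero_names=bundle.zero_names,
        term_slices=bundle.term_slices,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# diagnostics


def pearson_residuals(fit: FittedZINB, bundle: DesignBundle) -> np.ndarray:
    """Pearson residuals under the fitted ZINB mean/variance."""
    mu = np.exp(bundle.count_X @ fit.count_params)
    pi = special.expit(bundle.zero_X @ fit.zero_params)
    mean = (1 - pi) * mu
    var = (1 - pi) * mu * (1 + mu * (fit.alpha + pi))
    return (bundle.y - mean) / np.sqrt(var)


def residual_acf(resid: np.ndarray, nlags: int = 30) -> np.ndarray:
    """Autocorrelation function of a residual series (lags 0..nlags)."""
    from statsmodels.tsa.stattools import acf

    return acf(resid, nlags=nlags, fft=True)


def coefficient_table(fit: FittedZINB) -> pd.DataFrame:
    """Labeled summary: term, estimate, SE, and RR for count terms."""
    se = np.sqrt(np.diag(fit.covariance))
    labels = fit.param_labels()
    est = np.concatenate([fit.count_params, fit.zero_params, [np.log(fit.alpha)]])
    rr = [
        np.exp(e) if lbl.startswith("count:") else np.nan
        for e, lbl in zip(est, labels)
    ]
    return pd.DataFrame(
        {"term": labels, "estimate": est, "se": se, "rr": rr}
    )
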