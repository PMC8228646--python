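"""Multiple imputation of length of stay by predictive mean matching (PMM),
with Rubin's rules for pooling downstream estimates.

PMM here is the "proper" Bayesian variant: for each imputed dataset a
fresh draw of the linear-regression parameters (coefficients and
residual variance) is taken from their approximate posterior given the
complete cases; predictive means under the *drawn* parameters for the
missing records are matched against predictive means under the *fitted*
parameters for the complete cases (type-1 matching), and the observed
length of stay of one of the ``k`` nearest donors is copied.  Because
donors are observed values, imputations are automatically non-negative
integers like the real data.

Rubin's rules combine an estimate computed on each completed dataset:
the pooled point is the mean, and the pooled variance adds the average
within-imputation variance and the between-imputation spread inflated
by ``(1 + 1/m)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .records import AdmissionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationResult",
    "PooledEstimate",
    "pmm_impute",
    "pool_rubin",
    "pool_rubin_vector",
]

#: Default imputation predictors, in the order expected in record covariates.
DEFAULT_PREDICTORS = (
    "day_of_year",
    "day_of_week",
    "week",
    "month",
    "year",
    "season",
    "temp_min",
    "temp_mean",
    "temp_max",
    "rh_min",
    "rh_mean",
    "rh_max",
)


@dataclass
class ImputationResult:
    """``m`` completed record lists; observed values are shared, imputed differ."""

    completed_datasets: list[list[AdmissionRecord]]
    m: int
    seed: int


@dataclass
class PooledEstimate:
    """Rubin-pooled scalar estimate.

    ``total_var = within_var + (1 + 1/m) * between_var``; ``dof`` is the
    large-sample Rubin degrees of freedom (infinite when the estimates
    agree exactly across imputations).
    """

    point: float
    within_var: float
    between_var: float
    total_var: float
    dof: float
    m: int

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats

        se = np.sqrt(self.total_var)
        if np.isinf(self.dof):
            q = stats.norm.ppf(0.5 + level / 2)
        else:
            q = stats.t.ppf(0.5 + level / 2, self.dof)
        return (self.point - q * se, self.point + q * se)


def _design(records: list[AdmissionRecord], predictors: tuple[str, ...]):
    X = np.column_stack(
        [np.ones(len(records))]
        + [np.array([r.covariates.get(p, np.nan) for r in records]) for p in predictors]
    )
    if np.isnan(X).any():
        bad = [
            p
            for j, p in enumerate(predictors)
            if np.isnan(X[:, j + 1]).any()
        ]
        raise ValueError(f"predictors missing for some records: {bad}")
    return X


def pmm_impute(
    records: list[AdmissionRecord],
    predictor_names=DEFAULT_PREDICTORS,
    m: int = 20,
    k_donors: int = 5,
    seed: int = 0,
) -> ImputationResult:
    """Multiply impute missing length of stay by predictive mean matching.

    Each of the ``m`` imputations has its own RNG stream spawned from
    ``seed`` and the imputation index, so increasing ``m`` extends the
    set without reshuffling earlier imputations.  Constant predictor
    columns are dropped with a warning; at least ``k_donors`` complete
    cases are required.
    """
    predictors = tuple(predictor_names)
    obs_idx = [i for i, r in enumerate(records) if r.length_of_stay is not None]
    mis_idx = [i for i, r in enumerate(records) if r.length_of_stay is None]
    if not obs_idx:
        raise ValueError("no complete cases to learn the imputation model from")
    if len(obs_idx) < k_donors:
        raise ValueError(
            f"need at least k_donors={k_donors} complete cases, have {len(obs_idx)}"
        )
    if not mis_idx:
        return ImputationResult([list(records) for _ in range(m)], m, seed)

    X = _design(records, predictors)
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    if len(keep) < X.shape[1]:
        dropped = [predictors[j - 1] for j in range(1, X.shape[1]) if j not in keep]
        warnings.warn(f"dropping constant predictor columns: {dropped}")
        X = X[:, keep]

    y_obs = np.array([records[i].length_of_stay for i in obs_idx], dtype=float)
    X_obs = X[obs_idx]
    X_mis = X[mis_idx]
    n_obs, p = X_obs.shape

    # complete-case least squares (the matching side of type-1 PMM)
    beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n_obs - p, 1)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    # eigen square root: tolerant of collinear predictors (pinv null space)
    evals, evecs = np.linalg.eigh((xtx_inv + xtx_inv.T) / 2)
    xtx_inv_sqrt = evecs * np.sqrt(np.clip(evals, 0.0, None))
    yhat_obs = X_obs @ beta_hat

    datasets: list[list[AdmissionRecord]] = []
    for imp in range(m):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(imp,)))
        # posterior draw of (sigma^2, beta)
        sigma2 = s2 * dof / rng.chisquare(dof)
        beta_star = beta_hat + np.sqrt(sigma2) * (xtx_inv_sqrt @ rng.standard_normal(p))
        yhat_mis = X_mis @ beta_star
        completed = list(records)
        for row, i in enumerate(mis_idx):
            d = np.abs(yhat_obs - yhat_mis[row])
            donors = np.argpartition(d, k_donors - 1)[:k_donors]
            pick = donors[rng.integers(len(donors))]
            completed[i] = replace(records[i], length_of_stay=int(y_obs[pick]))
        datasets.append(completed)
    return ImputationResult(datasets, m, seed)


def pool_rubin(point_estimates, variances) -> PooledEstimate:
    """Pool ``m`` estimates and their variances by Rubin's rules."""
    q = np.asarray(point_estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-d and conformable")
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 (between-variance undefined)")
    if (u < 0).any():
        raise ValueError("variances must be non-negative")
    point = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1 + 1 / m) * between
    if between == 0:
        dof = np.inf
    else:
        r = (1 + 1 / m) * between
        dof = (m - 1) * (1 + within / r) ** 2
    return PooledEstimate(point, within, between, total, dof, m)


def pool_rubin_vector(coef_matrix, cov_list):
    """Rubin pooling of coefficient vectors with full covariance matrices.

    Returns ``(pooled_coefs, pooled_cov)`` where the pooled covariance is
    the mean within-imputation covariance plus ``(1 + 1/m)`` times the
    between-imputation covariance of the coefficient vectors.
    """
    Q = np.asarray(coef_matrix, dtype=float)
    if Q.ndim != 2 or Q.shape[0] < 2:
        raise ValueError("need an (m, p) coefficient matrix with m >= 2")
    m = Q.shape[0]
    if len(cov_list) != m:
        raise ValueError("one covariance matrix per imputation required")
    point = Q.mean(axis=0)
    within = np.mean(np.asarray(cov_list, dtype=float), axis=0)
    dev = Q - point
    between = dev.T @ dev / (m - 1)
    total = within + (1 + 1 / m) * between
    return point, total
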