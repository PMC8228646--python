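"""Natural cubic spline bases and exposure-lag crossbases.

The crossbasis is the design-matrix embedding of a distributed lag
non-linear model (DLNM): a tensor product of a spline basis over the
exposure value and a spline basis over the lag dimension, summed over
the lag window.  Row ``t``, column ``(i, j)`` of the crossbasis is

    sum_{l=0..L} B_x,i(x_{t-l}) * B_l,j(l)

so that a linear model on these columns represents a smooth
exposure-lag-response surface.

Natural cubic splines are cubic B-splines constrained to have zero
second derivative at (and hence be linear beyond) their boundary knots.
The basis here follows the classical construction: evaluate the full
cubic B-spline basis, then project onto the null space of the boundary
second-derivative constraints.  Dimension is
``#internal_knots + 1 (+1 with intercept)``; evaluation beyond the
boundary knots extrapolates linearly, which matters when predicting
under exposure-shift scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasis",
    "ns_basis",
    "crossbasis",
    "lag_basis_matrix",
    "lag_spline_spec",
]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a natural cubic spline basis.

    Parameters
    ----------
    internal_knots
        Strictly increasing knots strictly inside the boundary interval.
    boundary_knots
        ``(lower, upper)`` pair bracketing the internal knots; the basis
        is linear beyond these.
    intercept
        If True the basis spans the constant function (one extra column).
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.internal_knots)
        bk = (float(self.boundary_knots[0]), float(self.boundary_knots[1]))
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", bk)
        if not np.all(np.isfinite(ik)) or not np.all(np.isfinite(bk)):
            raise ValueError("knots must be finite")
        if bk[0] >= bk[1]:
            raise ValueError("boundary knots must satisfy lower < upper")
        if any(ik[i] >= ik[i + 1] for i in range(len(ik) - 1)):
            raise ValueError("internal knots must be strictly increasing")
        if ik and (ik[0] <= bk[0] or ik[-1] >= bk[1]):
            raise ValueError("boundary knots must strictly bracket internal knots")

    @property
    def ndim(self) -> int:
        """Number of basis columns."""
        return len(self.internal_knots) + 1 + (1 if self.intercept else 0)

    @classmethod
    def from_data(
        cls,
        x,
        n_knots: int = 3,
        intercept: bool = False,
        boundary: tuple[float, float] | None = None,
    ) -> "SplineSpec":
        """Place ``n_knots`` internal knots at equally spaced percentiles.

        With the default ``n_knots=3`` this is the 25th/50th/75th
        percentile rule conventional in DLNM work; boundaries default to
        the observed min/max.
        """
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError("no finite data to place knots on")
        if boundary is None:
            boundary = (float(np.min(x)), float(np.max(x)))
        probs = np.linspace(0.0, 100.0, n_knots + 2)[1:-1]
        knots = np.percentile(x, probs)
        eps = 1e-9 * (boundary[1] - boundary[0])
        knots = np.clip(knots, boundary[0] + eps, boundary[1] - eps)
        # collapse duplicate percentiles (heavily tied data)
        knots = tuple(np.unique(np.round(knots, 12)))
        return cls(knots, boundary, intercept=intercept)


def lag_spline_spec(max_lag: int, n_knots: int = 2) -> SplineSpec | None:
    """Default lag-dimension basis over integer lags ``0..max_lag``.

    Natural cubic spline *with* intercept and internal knots equally
    spaced on the log(1 + lag) scale, reflecting that lag structure is
    usually richer at short delays.  ``max_lag == 0`` returns ``None``,
    the marker for an intercept-only (unlagged) basis.
    """
    if max_lag == 0:
        return None
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    log_knots = np.linspace(0.0, np.log1p(max_lag), n_knots + 2)[1:-1]
    knots = tuple(np.expm1(log_knots))
    return SplineSpec(knots, (0.0, float(max_lag)), intercept=True)


@lru_cache(maxsize=None)
def _ns_operator(spec: SplineSpec):
    """B-spline machinery for a spec: (bspline, kept-column slice, null-space)."""
    bl, br = spec.boundary_knots
    t = np.concatenate([[bl] * 4, spec.internal_knots, [br] * 4])
    m = len(spec.internal_knots) + 4
    bs = BSpline(t, np.eye(m), 3, extrapolate=False)
    keep = slice(None) if spec.intercept else slice(1, None)
    # second derivatives at the boundaries: the natural constraints
    const = bs(np.array([bl, br]), 2)[:, keep]
    q, _ = np.linalg.qr(const.T, mode="complete")
    null = q[:, 2:]
    d_lo = (bs(np.array([bl]), 1)[:, keep] @ null)[0]
    d_hi = (bs(np.array([br]), 1)[:, keep] @ null)[0]
    v_lo = (bs(np.array([bl]))[:, keep] @ null)[0]
    v_hi = (bs(np.array([br]))[:, keep] @ null)[0]
    return bs, keep, null, (v_lo, d_lo), (v_hi, d_hi)


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an ``(len(x), spec.ndim)`` matrix.  Points beyond the
    boundary knots are evaluated by linear extrapolation (first-order
    Taylor expansion at the boundary), which is exact for a natural
    spline.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size == 0:
        raise ValueError("cannot evaluate spline basis on empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in spline input")
    bs, keep, null, (v_lo, d_lo), (v_hi, d_hi) = _ns_operator(spec)
    bl, br = spec.boundary_knots
    xc = np.clip(x, bl, br)
    out = bs(xc)[:, keep] @ null
    below = x < bl
    above = x > br
    if np.any(below):
        out[below] = v_lo + np.outer(x[below] - bl, d_lo)
    if np.any(above):
        out[above] = v_hi + np.outer(x[above] - br, d_hi)
    return out


def lag_basis_matrix(lag_spec: SplineSpec | None, max_lag: int) -> np.ndarray:
    """Lag basis evaluated at integer lags ``0..max_lag``.

    ``lag_spec=None`` denotes the degenerate intercept-only basis used
    for unlagged exposures (a single column of ones), so the same
    crossbasis code path serves lagged and same-day-only terms.
    """
    if lag_spec is None:
        return np.ones((max_lag + 1, 1))
    return ns_basis(np.arange(max_lag + 1, dtype=float), lag_spec)


@dataclass
class CrossBasis:
    """Exposure-lag crossbasis matrix plus the metadata to rebuild it.

    ``matrix`` has shape ``(n_days, v_x * v_l)`` with column ``(i, j)``
    at flat index ``i * v_l + j``.  Rows before ``valid_from`` lack a
    complete lag history; they are stored as zeros and must be excluded
    from any likelihood (``valid_from`` is the first usable row).
    """

    matrix: np.ndarray
    exposure_spec: SplineSpec
    lag_spec: SplineSpec | None
    max_lag: int
    valid_from: int
    source_name: str = ""

    @property
    def n_exposure_basis(self) -> int:
        return self.exposure_spec.ndim

    @property
    def n_lag_basis(self) -> int:
        return 1 if self.lag_spec is None else self.lag_spec.ndim

    def column_names(self) -> list[str]:
        vl = self.n_lag_basis
        return [
            f"{self.source_name}.x{i + 1}l{j + 1}"
            for i in range(self.n_exposure_basis)
            for j in range(vl)
        ]

    def meta(self) -> dict:
        """Serializable construction metadata (reproducibility contract)."""
        return {
            "source_name": self.source_name,
            "max_lag": self.max_lag,
            "valid_from": self.valid_from,
            "exposure_knots": list(self.exposure_spec.internal_knots),
            "exposure_boundary": list(self.exposure_spec.boundary_knots),
            "exposure_intercept": self.exposure_spec.intercept,
            "lag_knots": None if self.lag_spec is None else list(self.lag_spec.internal_knots),
            "lag_boundary": None if self.lag_spec is None else list(self.lag_spec.boundary_knots),
            "lag_intercept": None if self.lag_spec is None else self.lag_spec.intercept,
            "column_order": self.column_names(),
        }


def crossbasis(
    exposure_series,
    max_lag: int,
    exposure_spec: SplineSpec,
    lag_spec: SplineSpec | None = None,
    source_name: str = "",
) -> CrossBasis:
    """Build the exposure-lag crossbasis of a daily exposure series.

    Entry ``(t, i*v_l + j) = sum_{l=0..max_lag} B_x,i(x_{t-l}) B_l,j(l)``.
    Rows ``t < max_lag`` have incomplete history and are zeroed; use
    ``valid_from`` to exclude them downstream.
    """
    x = np.asarray(exposure_series, dtype=float)
    if x.ndim != 1:
        raise ValueError("exposure series must be one-dimensional")
    if x.size <= max_lag:
        raise ValueError(
            f"series length {x.size} must exceed max_lag {max_lag}"
        )
    bx = ns_basis(x, exposure_spec)
    bl = lag_basis_matrix(lag_spec, max_lag)
    n, vx = bx.shape
    vl = bl.shape[1]
    out = np.zeros((n, vx, vl))
    for lag in range(max_lag + 1):
        shifted = np.zeros_like(bx)
        shifted[lag:] = bx[: n - lag]
        out += shifted[:, :, None] * bl[lag][None, None, :]
    mat = out.reshape(n, vx * vl)
    mat[:max_lag] = 0.0
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite entries in crossbasis")
    return CrossBasis(
        matrix=mat,
        exposure_spec=exposure_spec,
        lag_spec=lag_spec,
        max_lag=max_lag,
        valid_from=max_lag,
        source_name=source_name,
    )
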