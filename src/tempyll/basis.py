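"""Spline bases and the temperature x lag cross-basis.

The exposure-lag-response surface of a distributed lag nonlinear model
(DLNM) is parameterized by the tensor product of two one-dimensional
spline bases: one over the exposure (daily mean temperature) and one over
the lag dimension (days since exposure, 0..L).  This module builds both
1-D bases and their cross-basis expansion.

Two spline families are supported:

* ``bspline`` — B-splines of configurable degree (default quadratic),
  evaluated with :class:`scipy.interpolate.BSpline`.  Without an intercept
  the first basis function is dropped, giving
  ``len(internal_knots) + degree`` columns.
* ``natural_cubic`` — natural cubic splines in the truncated-power
  parameterization: cubic between the boundary knots, second derivative
  zero at the boundaries, and therefore linear beyond them.  Columns:
  ``len(internal_knots) + 1`` plus one for the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasisMatrix",
    "quantile_knots",
    "spline_basis",
    "cross_basis",
    "lag_basis_column_sums",
    "default_var_spec",
    "default_lag_spec",
]

DEFAULT_KNOT_PERCENTILES = (27.5, 72.5)
DEFAULT_MAX_LAG = 21


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a one-dimensional spline basis.

    Parameters
    ----------
    family
        ``"natural_cubic"`` or ``"bspline"``.
    internal_knots
        Knot positions strictly inside the boundary knots, increasing.
    boundary_knots
        ``(lo, hi)`` pair delimiting the cubic (or polynomial) region.
    degree
        Polynomial degree, B-splines only (natural cubic is always cubic).
    intercept
        Whether the basis spans the constant function.
    """

    family: str
    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    degree: int = 2
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("natural_cubic", "bspline"):
            raise ValueError(f"unknown spline family: {self.family!r}")
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must satisfy lo < hi")
        ik = tuple(float(k) for k in self.internal_knots)
        if any(not lo < k < hi for k in ik):
            raise ValueError("internal knots must lie strictly inside boundaries")
        if any(b - a <= 0 for a, b in zip(ik, ik[1:])):
            raise ValueError("internal knots must be strictly increasing")
        if self.family == "bspline" and self.degree < 1:
            raise ValueError("bspline degree must be >= 1")
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def n_cols(self) -> int:
        n_int = len(self.internal_knots)
        if self.family == "bspline":
            n = n_int + self.degree
        else:
            n = n_int + 1
        return n + (1 if self.intercept else 0)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "internal_knots": list(self.internal_knots),
            "boundary_knots": list(self.boundary_knots),
            "degree": self.degree,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            family=d["family"],
            internal_knots=tuple(d["internal_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            degree=int(d.get("degree", 2)),
            intercept=bool(d.get("intercept", False)),
        )


def quantile_knots(x, percentiles=DEFAULT_KNOT_PERCENTILES) -> np.ndarray:
    """Empirical quantiles of ``x`` used as internal knot locations.

    Uses linear interpolation between order statistics.  Raises if the
    resulting knots are not strictly increasing (near-constant input).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot place knots on an empty vector")
    p = np.asarray(percentiles, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100) or np.any(np.diff(p) <= 0):
        raise ValueError("percentiles must be strictly increasing within (0, 100)")
    knots = np.quantile(x, p / 100.0, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"tied quantiles produce non-increasing knots: {knots}")
    return knots


def _bspline_design(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    lo, hi = spec.boundary_knots
    t = np.concatenate(
        [
            np.repeat(lo, spec.degree + 1),
            np.asarray(spec.internal_knots, dtype=float),
            np.repeat(hi, spec.degree + 1),
        ]
    )
    # design_matrix requires x inside the knot span; callers clamp out-of-range
    # values explicitly where that is the documented policy.
    xc = np.clip(x, lo, hi)
    dm = BSpline.design_matrix(xc, t, spec.degree, extrapolate=False).toarray()
    if not spec.intercept:
        dm = dm[:, 1:]
    return dm


def _natural_cubic_design(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    # Truncated-power parameterization: with knots xi_1 < ... < xi_M
    # (boundary + internal), basis = {1?, x, d_k(x) - d_{M-1}(x)} where
    # d_k(x) = [(x - xi_k)_+^3 - (x - xi_M)_+^3] / (xi_M - xi_k).
    # Linear below xi_1 and above xi_M by construction.
    lo, hi = spec.boundary_knots
    xi = np.concatenate([[lo], np.asarray(spec.internal_knots, dtype=float), [hi]])
    M = xi.size

    def d(k: int) -> np.ndarray:
        return (
            np.maximum(x - xi[k], 0.0) ** 3 - np.maximum(x - xi[M - 1], 0.0) ** 3
        ) / (xi[M - 1] - xi[k])

    cols = [x]
    d_last = d(M - 2)
    for k in range(M - 2):
        cols.append(d(k) - d_last)
    if spec.intercept:
        cols.insert(0, np.ones_like(x))
    return np.column_stack(cols)


def spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the basis described by ``spec`` at the points ``x``.

    Returns an ``(len(x), spec.n_cols)`` array.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("spline basis input contains non-finite values")
    if spec.family == "bspline":
        return _bspline_design(x, spec)
    return _natural_cubic_design(x, spec)


@dataclass(frozen=True)
class CrossBasisMatrix:
    """Day x (var-basis x lag-basis) design block of a DLNM.

    ``values[t, j*m + k] = sum_{l=0..L} B_var_j(x[t-l]) * B_lag_k(l)``,
    with partial sums (missing history treated as absent) for the first
    ``valid_from`` rows, which must be excluded from model fitting.
    """

    values: np.ndarray
    var_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int
    x: np.ndarray = field(repr=False)  # the exposure series that built it

    @property
    def valid_from(self) -> int:
        return self.max_lag

    @property
    def n_cols(self) -> int:
        return self.var_spec.n_cols * self.lag_spec.n_cols


def default_var_spec(temp, percentiles=DEFAULT_KNOT_PERCENTILES) -> SplineSpec:
    """Quadratic B-spline over the observed temperature range.

    Internal knots at the 27.5th/72.5th percentiles of the daily mean
    temperature distribution, boundary knots at the observed min/max,
    no intercept: 4 columns with the defaults.
    """
    temp = np.asarray(temp, dtype=float)
    knots = quantile_knots(temp, percentiles)
    return SplineSpec(
        family="bspline",
        internal_knots=tuple(knots),
        boundary_knots=(float(temp.min()), float(temp.max())),
        degree=2,
        intercept=False,
    )


def default_lag_spec(max_lag: int = DEFAULT_MAX_LAG, n_internal: int = 2) -> SplineSpec:
    """Natural cubic spline over lag 0..L with intercept.

    Internal knots equally spaced on the log(lag+1) scale, the customary
    choice that concentrates flexibility at short lags.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2 for a spline lag structure")
    u = np.linspace(0.0, np.log(max_lag + 1.0), n_internal + 2)[1:-1]
    knots = tuple(np.exp(u) - 1.0)
    return SplineSpec(
        family="natural_cubic",
        internal_knots=knots,
        boundary_knots=(0.0, float(max_lag)),
        intercept=True,
    )


def cross_basis(temp, var_spec: SplineSpec, lag_spec: SplineSpec, max_lag: int) -> CrossBasisMatrix:
    """Build the DLNM cross-basis of an exposure series.

    Row ``t``, column ``(j, k)`` (j-major order) holds
    ``sum_{l=0..max_lag} B_var_j(temp[t-l]) * B_lag_k(l)``.
    """
    temp = np.asarray(temp, dtype=float)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    n = temp.size
    if n <= max_lag:
        raise ValueError(f"series length {n} must exceed max_lag {max_lag}")
    A = spline_basis(temp, var_spec)  # n x v
    C = spline_basis(np.arange(max_lag + 1, dtype=float), lag_spec)  # (L+1) x m
    v, m = A.shape[1], C.shape[1]
    out = np.zeros((n, v * m))
    for l in range(max_lag + 1):
        # rows t >= l receive A[t-l, j] * C[l, k]
        contrib = A[: n - l, :, None] * C[l][None, None, :]  # (n-l) x v x m
        out[l:, :] += contrib.reshape(n - l, v * m)
    return CrossBasisMatrix(values=out, var_spec=var_spec, lag_spec=lag_spec, max_lag=max_lag, x=temp)


def lag_basis_column_sums(lag_spec: SplineSpec, max_lag: int) -> np.ndarray:
    """Column sums of the lag basis over integer lags 0..L.

    These are the weights that collapse the cross-basis coefficients into
    the overall (lag-cumulated) exposure-response curve.
    """
    C = spline_basis(np.arange(max_lag + 1, dtype=float), lag_spec)
    return C.sum(axis=0)
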