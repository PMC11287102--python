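"""City-level time-series regression of daily YLL on the temperature cross-basis.

Model (per city):

    YLL_t = alpha + CB(temp; var, lag) beta + NS(time, 7 df/year)
            + NS(rh, 3) + NS(sunshine, 3) + NS(ws, 3) + NS(ap, 3)
            + gamma DOW_t + delta Holiday_t + eps_t,   eps_t ~ N(0, sigma^2)

Daily YLL is approximately normal, so the "general linear regression with
Gaussian link" is ordinary least squares.  The fitted cross-basis block is
then reduced to the overall (lag-cumulated) exposure-response curve: a
length-v coefficient vector ``eta`` with covariance, which is what the
second-stage meta-analysis pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .basis import (
    CrossBasisMatrix,
    SplineSpec,
    cross_basis,
    default_lag_spec,
    default_var_spec,
    lag_basis_column_sums,
    spline_basis,
)
from .series import CityDailySeries

__all__ = [
    "FirstStageConfig",
    "FirstStageFit",
    "ReducedAssociation",
    "build_design",
    "fit_gaussian_glm",
    "reduce_to_overall",
    "predict_curve",
    "fit_city",
]

COVARIATES = ("rh", "sunshine", "ws", "ap")


@dataclass(frozen=True)
class FirstStageConfig:
    """Tunable surface of the first-stage model.

    ``time_df_per_year`` (default 7) controls seasonality/trend; the time
    spline gets ``round(time_df_per_year * n_years)`` df.  Each
    meteorological covariate gets a whole-period natural cubic spline with
    ``covariate_df`` (default 3) df.  ``max_lag`` (default 21 days) bounds
    the lag window; sensitivity analyses use 14 or 28.
    """

    time_df_per_year: float = 7.0
    covariate_df: int = 3
    max_lag: int = 21
    var_percentiles: tuple[float, float] = (27.5, 72.5)
    lag_internal_knots: int = 2

    def __post_init__(self) -> None:
        if self.time_df_per_year < 1 or self.covariate_df < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")


@dataclass
class FirstStageFit:
    """OLS fit with labeled coefficient blocks."""

    coefficients: np.ndarray
    vcov: np.ndarray
    residual_variance: float
    n_used: int
    column_blocks: list[str]  # block label per design column
    column_names: list[str]

    def block(self, name: str) -> np.ndarray:
        idx = [i for i, b in enumerate(self.column_blocks) if b == name]
        return self.coefficients[idx]

    def block_vcov(self, name: str) -> np.ndarray:
        idx = [i for i, b in enumerate(self.column_blocks) if b == name]
        return self.vcov[np.ix_(idx, idx)]


@dataclass
class ReducedAssociation:
    """Overall cumulative exposure-response curve of one city.

    ``eta`` (length v) and its covariance parameterize the lag-summed
    curve on the city's temperature basis; ``reference_temperature``
    centers predictions (the curve is 0 there by construction).
    """

    eta: np.ndarray
    vcov: np.ndarray
    var_spec: SplineSpec
    reference_temperature: float
    temp_percentiles: dict = field(default_factory=dict)  # {1: .., 50: .., 99: ..}
    temp_range: tuple[float, float] = (np.nan, np.nan)
    city_id: str = ""

    def curve(self, temps) -> np.ndarray:
        """Centered cumulative effect at the given temperatures."""
        B = spline_basis(np.asarray(temps, dtype=float), self.var_spec)
        B0 = spline_basis(np.array([self.reference_temperature]), self.var_spec)
        return (B - B0) @ self.eta


def _time_spline(n: int, df: int) -> np.ndarray:
    # time scaled to [0, 1] to keep truncated-power columns well conditioned
    t = np.linspace(0.0, 1.0, n)
    if df < 2:
        return t[:, None]
    internal = tuple(np.linspace(0.0, 1.0, df + 1)[1:-1])
    spec = SplineSpec(
        family="natural_cubic", internal_knots=internal, boundary_knots=(0.0, 1.0), intercept=False
    )
    return spline_basis(t, spec)


def _covariate_spline(x: np.ndarray, df: int) -> np.ndarray:
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    if not lo < hi:
        raise ValueError("constant covariate cannot be spline-expanded")
    if df < 2:
        return x[:, None]
    qs = np.linspace(0.0, 100.0, df + 1)[1:-1]
    internal = np.percentile(x[np.isfinite(x)], qs)
    if np.any(np.diff(np.concatenate([[lo], internal, [hi]])) <= 0):
        # fall back to equally spaced knots for heavily tied covariates
        internal = np.linspace(lo, hi, df + 1)[1:-1]
    spec = SplineSpec(
        family="natural_cubic",
        internal_knots=tuple(internal),
        boundary_knots=(lo, hi),
        intercept=False,
    )
    # missing days propagate as NaN rows and are listwise-excluded later
    finite = np.isfinite(x)
    out = np.full((x.size, spec.n_cols), np.nan)
    out[finite] = spline_basis(x[finite], spec)
    return out


def build_design(
    series: CityDailySeries, cb: CrossBasisMatrix, config: FirstStageConfig
):
    """Assemble the labeled design matrix and response.

    Returns ``(X, column_blocks, column_names, y, used_mask)``; rows are
    restricted to days with complete lag history and finite values.
    """
    n = len(series)
    if cb.values.shape[0] != n:
        raise ValueError("series and cross-basis are not aligned")
    n_years = n / 365.25
    if n_years < 1.0:
        raise ValueError("series must cover at least one year")
    time_df = int(round(config.time_df_per_year * n_years))

    blocks: list[tuple[str, np.ndarray]] = [("intercept", np.ones((n, 1)))]
    blocks.append(("crossbasis", cb.values))
    blocks.append(("time", _time_spline(n, time_df)))
    for cov in COVARIATES:
        blocks.append((cov, _covariate_spline(series.data[cov].to_numpy(dtype=float), config.covariate_df)))
    dow = series.dates.dayofweek.to_numpy()
    dow_block = np.column_stack([(dow == d).astype(float) for d in range(1, 7)])  # Monday ref
    blocks.append(("dow", dow_block))
    blocks.append(("holiday", series.data["holiday"].to_numpy(dtype=float)[:, None]))

    X = np.hstack([b for _, b in blocks])
    column_blocks: list[str] = []
    column_names: list[str] = []
    for name, b in blocks:
        for j in range(b.shape[1]):
            column_blocks.append(name)
            column_names.append(name if b.shape[1] == 1 else f"{name}[{j}]")

    y = series.yll
    used = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    used[: cb.valid_from] = False
    return X, column_blocks, column_names, y, used


def fit_gaussian_glm(y: np.ndarray, X: np.ndarray, column_blocks=None, column_names=None) -> FirstStageFit:
    """Ordinary least squares with covariance sigma^2 (X'X)^-1.

    The Gaussian identity-link GLM coincides with OLS, so no iterative
    fitting is needed; sigma^2 = RSS / (n - p).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite values in response or design")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * diag.max()
    if np.any(diag < tol):
        bad = [i for i in np.flatnonzero(diag < tol)]
        labels = (
            sorted({column_blocks[i] for i in bad}) if column_blocks is not None else bad
        )
        raise ValueError(f"rank-deficient design; collinear block(s): {labels}")
    beta = linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    Rinv = linalg.solve_triangular(R, np.eye(p))
    vcov = sigma2 * (Rinv @ Rinv.T)
    vcov = (vcov + vcov.T) / 2.0
    return FirstStageFit(
        coefficients=beta,
        vcov=vcov,
        residual_variance=sigma2,
        n_used=n,
        column_blocks=list(column_blocks) if column_blocks is not None else ["x"] * p,
        column_names=list(column_names) if column_names is not None else [f"x{i}" for i in range(p)],
    )


def reduce_to_overall(
    fit: FirstStageFit, cb: CrossBasisMatrix, reference: float, city_id: str = ""
) -> ReducedAssociation:
    """Collapse the cross-basis block to the overall cumulative curve.

    ``eta_j = sum_k beta_(j,k) * S_k`` with ``S_k`` the lag-basis column
    sums over integer lags; the covariance maps through the same linear
    transform.  ``B_var(x) @ eta`` is then the model-implied cumulative
    YLL change for sustained exposure at x over the whole lag window,
    relative to sustained exposure at the basis origin; predictions are
    centered at ``reference``.
    """
    lo, hi = cb.var_spec.boundary_knots
    if not lo <= reference <= hi:
        raise ValueError(f"reference {reference} outside basis boundaries [{lo}, {hi}]")
    v = cb.var_spec.n_cols
    m = cb.lag_spec.n_cols
    beta = fit.block("crossbasis")
    V = fit.block_vcov("crossbasis")
    if beta.size != v * m:
        raise ValueError("fit cross-basis block does not match the cross-basis dimensions")
    S = lag_basis_column_sums(cb.lag_spec, cb.max_lag)
    # T: (v x v*m), eta = T beta with columns ordered j-major
    T = np.zeros((v, v * m))
    for j in range(v):
        T[j, j * m : (j + 1) * m] = S
    eta = T @ beta
    vcov = T @ V @ T.T
    temps = cb.x
    pct = {q: float(np.percentile(temps, q)) for q in (1, 25, 50, 75, 99)}
    return ReducedAssociation(
        eta=eta,
        vcov=(vcov + vcov.T) / 2.0,
        var_spec=cb.var_spec,
        reference_temperature=float(reference),
        temp_percentiles=pct,
        temp_range=(float(temps.min()), float(temps.max())),
        city_id=city_id,
    )


def predict_curve(assoc: ReducedAssociation, temps) -> dict:
    """Centered cumulative effect with pointwise 95% CI at each temperature."""
    temps = np.asarray(temps, dtype=float)
    lo, hi = assoc.var_spec.boundary_knots
    if np.any(temps < lo) or np.any(temps > hi):
        raise ValueError(f"prediction temperatures outside basis boundaries [{lo}, {hi}]")
    B = spline_basis(temps, assoc.var_spec)
    B0 = spline_basis(np.array([assoc.reference_temperature]), assoc.var_spec)
    D = B - B0
    effect = D @ assoc.eta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, assoc.vcov, D), 0.0))
    return {
        "temp": temps,
        "effect": effect,
        "lo": effect - 1.96 * se,
        "hi": effect + 1.96 * se,
        "se": se,
    }


def fit_city(
    series: CityDailySeries,
    config: FirstStageConfig | None = None,
    reference: float | None = None,
    var_spec: SplineSpec | None = None,
) -> tuple[FirstStageFit, ReducedAssociation, CrossBasisMatrix]:
    """Convenience wrapper: cross-basis, design, OLS fit, reduction.

    The centering default is the city's 50th temperature percentile.
    A shared ``var_spec`` (e.g. built from pooled temperatures) makes the
    reduced coefficients directly comparable across cities; by default the
    basis is city-specific (knots at the city's own percentiles).
    """
    cfg = config or FirstStageConfig()
    if var_spec is None:
        var_spec = default_var_spec(series.temp, cfg.var_percentiles)
    lag_spec = default_lag_spec(cfg.max_lag, cfg.lag_internal_knots)
    cb = cross_basis(series.temp, var_spec, lag_spec, cfg.max_lag)
    X, blocks, names, y, used = build_design(series, cb, cfg)
    fit = fit_gaussian_glm(y[used], X[used], blocks, names)
    ref = float(np.percentile(series.temp, 50)) if reference is None else reference
    assoc = reduce_to_overall(fit, cb, ref, city_id=series.city_id)
    return fit, assoc, cb
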