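"""Multivariate random-effects meta-analysis / meta-regression of city curves.

Pools the city-specific reduced-curve coefficient vectors ``eta_i`` (with
within-city covariances ``S_i``) under the model

    eta_i ~ N(X_i mu, S_i + Psi),

estimated by maximum likelihood with ``mu`` profiled out (GLS given Psi)
and the between-city covariance ``Psi`` optimized on a Cholesky
parameterization, which keeps it positive semidefinite.  Heterogeneity is
quantified by the multivariate Cochran Q against the fixed-effects fit
and I^2 = max(0, (Q - df)/Q) * 100; a city-level meta-predictor entering
one at a time is tested by a Wald chi-square on its v coefficients; model
fit is compared by AIC; per-city curves are shrunk toward the pooled mean
by best linear unbiased prediction (BLUP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "MetaInput",
    "MetaFit",
    "mvmeta_fit",
    "cochran_q",
    "i_squared",
    "wald_test",
    "aic",
    "blup",
]

_MAX_ITER = 500
_GTOL = 1e-6


@dataclass
class MetaInput:
    """Per-city curve coefficients and covariances, plus meta-predictors.

    ``etas`` is (k, v); ``covs`` is (k, v, v); ``predictors`` maps a
    predictor name to its length-k value vector.
    """

    etas: np.ndarray
    covs: np.ndarray
    city_ids: list[str] | None = None
    predictors: dict | None = None

    def __post_init__(self) -> None:
        self.etas = np.atleast_2d(np.asarray(self.etas, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim == 2:
            self.covs = self.covs[None, :, :]
        k, v = self.etas.shape
        if self.covs.shape != (k, v, v):
            raise ValueError(f"covs shape {self.covs.shape} does not match etas {self.etas.shape}")
        for i in range(k):
            S = self.covs[i]
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError(f"city {i}: covariance not symmetric")
            if np.min(np.linalg.eigvalsh((S + S.T) / 2)) < -1e-8 * max(1.0, np.abs(S).max()):
                raise ValueError(f"city {i}: covariance not positive semidefinite")
        if self.city_ids is None:
            self.city_ids = [f"city{i + 1:02d}" for i in range(k)]

    @property
    def k(self) -> int:
        return self.etas.shape[0]

    @property
    def v(self) -> int:
        return self.etas.shape[1]


@dataclass
class MetaFit:
    """Result of a multivariate meta-regression fit."""

    mu: np.ndarray          # (p, v) pooled coefficients; row 0 = intercept
    mu_vcov: np.ndarray     # (p*v, p*v)
    psi: np.ndarray         # (v, v) between-city covariance
    loglik: float
    aic: float
    q: float
    q_df: int
    q_p: float
    i2_percent: float
    predictor: str | None = None
    wald: tuple | None = None          # (W, df, p) for the predictor block
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = 0.0
    psi_estimated: bool = True

    @property
    def pooled(self) -> np.ndarray:
        """Intercept row: the pooled curve coefficients."""
        return self.mu[0]


def _design(minput: MetaInput, predictor: str | None) -> np.ndarray:
    k = minput.k
    if predictor is None:
        return np.ones((k, 1))
    if not minput.predictors or predictor not in minput.predictors:
        raise KeyError(f"meta-predictor {predictor!r} not provided")
    x = np.asarray(minput.predictors[predictor], dtype=float)
    if x.shape != (k,):
        raise ValueError(f"predictor {predictor!r} must have one value per city")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"predictor {predictor!r} has non-finite values")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError(f"predictor {predictor!r} is constant across cities")
    # z-standardized: Wald statistics are invariant to this, the optimizer
    # is not scale-invariant in practice
    z = (x - x.mean()) / sd
    return np.column_stack([np.ones(k), z])


def _gls(etas, covs, X, psi):
    """Profile GLS of mu given Psi; returns (b, U_inv, loglik, resids, Ws).

    Batched over cities: with Z_i = x_i (kron) I_v, the normal equations
    are U = sum_i (x_i x_i') (kron) W_i and c = sum_i x_i (kron) W_i eta_i
    where W_i = (S_i + Psi)^-1.
    """
    k, v = etas.shape
    p = X.shape[1]
    V = covs + psi[None, :, :]
    V = (V + np.swapaxes(V, 1, 2)) / 2.0
    L = np.linalg.cholesky(V)  # raises LinAlgError if any V_i not PD
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
    W = np.linalg.solve(V, np.broadcast_to(np.eye(v), (k, v, v)).copy())
    U = np.einsum("ka,kb,kuw->aubw", X, X, W).reshape(p * v, p * v)
    Wy = np.einsum("kuw,kw->ku", W, etas)
    c = np.einsum("ka,ku->au", X, Wy).reshape(p * v)
    U_inv = np.linalg.inv(U)
    b = U_inv @ c
    resids = etas - X @ b.reshape(p, v)
    quad = float(np.einsum("ku,kuw,kw->", resids, W, resids))
    loglik = -0.5 * (k * v * np.log(2.0 * np.pi) + logdet + quad)
    return b, U_inv, loglik, resids, W


def _theta_to_psi(theta: np.ndarray, v: int) -> np.ndarray:
    L = np.zeros((v, v))
    L[np.diag_indices(v)] = np.exp(theta[:v])
    if v > 1:
        L[np.tril_indices(v, -1)] = theta[v:]
    return L @ L.T


def _psi_start(minput: MetaInput) -> np.ndarray:
    emp = np.cov(minput.etas, rowvar=False, ddof=1) if minput.k > 1 else np.zeros((minput.v, minput.v))
    emp = np.atleast_2d(emp)
    start = emp - minput.covs.mean(axis=0)
    w, Q = np.linalg.eigh((start + start.T) / 2.0)
    floor = max(1e-4, 1e-3 * np.trace(minput.covs.mean(axis=0)) / minput.v)
    return (Q * np.maximum(w, floor)) @ Q.T


def mvmeta_fit(
    minput: MetaInput,
    predictor: str | None = None,
    method: str = "ml",
    psi: str = "estimate",
) -> MetaFit:
    """Fit the multivariate meta-regression by maximum likelihood.

    ``predictor=None`` gives the intercept-only pooled model; naming one
    meta-predictor adds its (z-standardized) linear term.  ``psi="zero"``
    fixes the between-city covariance at 0 (fixed-effects GLS) — also the
    single-city degenerate case, where the pooled estimate is that city's
    own curve.
    """
    if method != "ml":
        raise ValueError("only maximum likelihood estimation is supported")
    if psi not in ("estimate", "zero"):
        raise ValueError("psi must be 'estimate' or 'zero'")
    X = _design(minput, predictor)
    k, v, p = minput.k, minput.v, X.shape[1]
    if psi == "estimate" and k <= p:
        raise ValueError(f"need more cities ({k}) than predictor terms ({p}) to estimate Psi")
    if k < p:
        raise ValueError(f"need at least as many cities ({k}) as predictor terms ({p})")

    n_iter = 0
    grad_norm = 0.0
    converged = True
    if psi == "zero":
        psi_hat = np.zeros((v, v))
        psi_estimated = False
    else:
        psi_estimated = True

        def nll(theta):
            P = _theta_to_psi(theta, v)
            try:
                _, _, ll, _, _ = _gls(minput.etas, minput.covs, X, P)
            except np.linalg.LinAlgError:
                return 1e12
            return -ll

        P0 = _psi_start(minput)
        L0 = np.linalg.cholesky(P0 + 1e-10 * np.eye(v))
        theta0 = np.concatenate([np.log(np.diag(L0)), L0[np.tril_indices(v, -1)]])
        res = optimize.minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": _MAX_ITER, "gtol": _GTOL, "ftol": 1e-12},
        )
        n_iter = int(res.nit)
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        psi_hat = _theta_to_psi(res.x, v)
        if not res.success and n_iter >= _MAX_ITER:
            raise RuntimeError(
                f"meta-regression did not converge after {_MAX_ITER} iterations "
                f"(grad norm {grad_norm:.2e}); best Psi trace {np.trace(psi_hat):.3g}"
            )
        converged = bool(res.success)

    b, U_inv, loglik, _, _ = _gls(minput.etas, minput.covs, X, psi_hat)
    mu = b.reshape(p, v)
    n_par = p * v + (v * (v + 1) // 2 if psi_estimated else 0)
    aic_value = -2.0 * loglik + 2.0 * n_par

    q, q_df, q_p = _cochran_q_raw(minput, X)
    fit = MetaFit(
        mu=mu,
        mu_vcov=U_inv,
        psi=psi_hat,
        loglik=float(loglik),
        aic=float(aic_value),
        q=q,
        q_df=q_df,
        q_p=q_p,
        i2_percent=i_squared(q, q_df) if q_df >= 1 else np.nan,
        predictor=predictor,
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        psi_estimated=psi_estimated,
    )
    if predictor is not None:
        fit.wald = wald_test(fit)
    return fit


def _cochran_q_raw(minput: MetaInput, X: np.ndarray):
    k, v = minput.k, minput.v
    p = X.shape[1]
    for i in range(k):
        if np.linalg.matrix_rank(minput.covs[i]) < v:
            raise ValueError(f"singular within-city covariance for {minput.city_ids[i]}")
    _, _, _, resids, Ws = _gls(minput.etas, minput.covs, X, np.zeros((v, v)))
    q = float(sum(resids[i] @ Ws[i] @ resids[i] for i in range(k)))
    q_df = k * v - p * v
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
    return q, q_df, q_p


def cochran_q(minput: MetaInput, predictor: str | None = None):
    """Multivariate Cochran Q: fixed-effects residual heterogeneity.

    ``Q = sum_i r_i' S_i^-1 r_i`` with residuals from the Psi=0 GLS fit of
    the same predictor structure; df = k*v - p*v; p-value from the
    chi-square upper tail.  Requires k >= 2 cities.
    """
    if minput.k < 2:
        raise ValueError("heterogeneity statistics need at least 2 cities")
    X = _design(minput, predictor)
    return _cochran_q_raw(minput, X)


def i_squared(q: float, df: int) -> float:
    """I^2 (%) = max(0, (Q - df)/Q) * 100."""
    if q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if q == 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def wald_test(fit: MetaFit):
    """Wald chi-square on the meta-predictor's v coefficients.

    ``W = b' V_b^-1 b`` with df = v; requires a fit with exactly one
    non-intercept predictor.
    """
    p, v = fit.mu.shape
    if p != 2:
        raise ValueError("Wald test needs a fit with exactly one non-intercept predictor")
    b = fit.mu[1]
    Vb = fit.mu_vcov[v : 2 * v, v : 2 * v]
    try:
        W = float(b @ np.linalg.solve(Vb, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular predictor-coefficient covariance") from exc
    return W, v, float(stats.chi2.sf(W, v))


def aic(fit: MetaFit) -> float:
    """AIC = -2 loglik + 2 (#mean parameters + #free Psi parameters)."""
    return fit.aic


def blup(minput: MetaInput, fit: MetaFit):
    """Best linear unbiased predictions of each city's curve coefficients.

    ``blup_i = m_i + Psi (Psi + S_i)^-1 (eta_i - m_i)`` with ``m_i`` the
    fitted mean; the returned covariance is the contracted conditional
    covariance ``Psi - Psi (Psi + S_i)^-1 Psi`` plus the propagated
    uncertainty of the fitted mean, ``(I - A) Z_i V_mu Z_i' (I - A)'``.
    With Psi = 0 every BLUP equals the pooled mean; as S_i -> 0 a city's
    BLUP approaches its own estimate.
    """
    k, v = minput.k, minput.v
    p = fit.mu.shape[0]
    if fit.predictor is None:
        X = np.ones((k, 1))
    else:
        X = _design(minput, fit.predictor)
    if X.shape[1] != p:
        raise ValueError("fit and input predictor structures disagree")
    out = []
    for i in range(k):
        m = X[i] @ fit.mu
        V = minput.covs[i] + fit.psi
        cf = linalg.cho_factor((V + V.T) / 2.0 + 1e-12 * np.eye(v))
        A = fit.psi @ linalg.cho_solve(cf, np.eye(v))
        eta_b = m + A @ (minput.etas[i] - m)
        Z = np.kron(X[i], np.eye(v))
        IA = np.eye(v) - A
        vcov_b = fit.psi - A @ fit.psi + IA @ Z @ fit.mu_vcov @ Z.T @ IA.T
        out.append((eta_b, (vcov_b + vcov_b.T) / 2.0))
    return out
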