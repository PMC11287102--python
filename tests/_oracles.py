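"""Independent reference implementations used only as test oracles.

Deliberately written as direct textbook formulas / explicit loops so they
share no code path with the package.
"""

import numpy as np


def cox_de_boor_basis(x, knots, degree):
    """All B-spline basis functions on the full knot vector by the raw
    Cox-de-Boor recursion (0/0 := 0); right-closed at the last knot."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(knots, dtype=float)
    n_funcs = len(t) - degree - 1
    last = t[-1]
    N = np.zeros((x.size, len(t) - 1))
    for i in range(len(t) - 1):
        N[:, i] = ((t[i] <= x) & (x < t[i + 1])).astype(float)
        if t[i] < t[i + 1] == last:
            N[x == last, i] = 1.0
    for d in range(1, degree + 1):
        N_next = np.zeros((x.size, len(t) - 1 - d))
        for i in range(len(t) - 1 - d):
            term = np.zeros(x.size)
            if t[i + d] > t[i]:
                term += (x - t[i]) / (t[i + d] - t[i]) * N[:, i]
            if t[i + d + 1] > t[i + 1]:
                term += (t[i + d + 1] - x) / (t[i + d + 1] - t[i + 1]) * N[:, i + 1]
            N_next[:, i] = term
        N = N_next
    return N[:, :n_funcs]


def quantile_by_sorting(x, p_percent):
    """Linear interpolation between order statistics, written out."""
    xs = np.sort(np.asarray(x, dtype=float))
    h = (len(xs) - 1) * (p_percent / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def cross_basis_double_loop(temp, var_basis_at, lag_basis_rows, max_lag):
    """values[t, j*m+k] = sum_l B_var_j(temp[t-l]) * B_lag_k(l), explicit."""
    n = len(temp)
    v = var_basis_at(temp[:1]).shape[1]
    m = lag_basis_rows.shape[1]
    out = np.zeros((n, v * m))
    for t in range(n):
        for j in range(v):
            for k in range(m):
                s = 0.0
                for l in range(max_lag + 1):
                    if t - l >= 0:
                        s += var_basis_at(np.array([temp[t - l]]))[0, j] * lag_basis_rows[l, k]
                out[t, j * m + k] = s
    return out


def ols_normal_equations(y, X):
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (X.shape[0] - X.shape[1])
    return beta, sigma2 * np.linalg.inv(XtX)


def inverse_variance_mean(y, variances):
    w = 1.0 / np.asarray(variances, dtype=float)
    return float(np.sum(w * y) / np.sum(w))


def scalar_empirical_bayes_blup(y_i, s_i, mu, psi):
    """Shrinkage of a scalar study estimate toward the pooled mean."""
    lam = psi / (psi + s_i)
    return mu + lam * (y_i - mu)
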