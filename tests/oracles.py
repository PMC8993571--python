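"""Independent brute-force reference implementations used to cross-check the
package's statistics. These deliberately avoid the code paths under test:
closed-form normal equations, hand-rolled Newton-Raphson, textbook count
formulas, and a direct just-identified IV solve."""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_normal_equations(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and classical SEs from the normal equations."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se


def logistic_newton(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-12, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic regression by full Newton-Raphson with observed information SEs."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return beta, np.sqrt(np.diag(cov))


def hwe_chi2_from_counts(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """Textbook Hardy-Weinberg Pearson chi-square (1 df) from genotype counts."""
    n = n0 + n1 + n2
    p = (n1 + 2 * n2) / (2 * n)
    q = 1 - p
    e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
    chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    return chi2, stats.chi2.sf(chi2, 1)


def pearson_chi2_contingency(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for an r x c contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, stats.chi2.sf(chi2, df)


def iv_2sls_single_instrument(
    y: np.ndarray, x: np.ndarray, z: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Just-identified two-stage least squares point estimate for the exposure
    coefficient, with covariates included in both stages."""
    n = len(y)
    const = np.ones((n, 1))
    W = const if covariates is None else np.column_stack([const, covariates])
    Z = np.column_stack([z, W])
    X = np.column_stack([x, W])
    beta = np.linalg.solve(Z.T @ X, Z.T @ y)
    return float(beta[0])
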