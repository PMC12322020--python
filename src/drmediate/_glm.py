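"""Lean weighted-logistic and Poisson fits used inside bootstrap loops.

These are straight Fisher-scoring (IRLS) maximum-likelihood fits on dense numpy
arrays.  They exist because the doubly robust bootstrap refits two GLMs per
replicate across hundreds of replicates and cohorts; the unit tests pin them to
statsmodels GLM output to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """Fitted probabilities numerically 0/1 (quasi-separation)."""

    def __init__(self, n_extreme: int):
        super().__init__(f"quasi-separation: {n_extreme} fitted probabilities at 0/1")
        self.n_extreme = n_extreme


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Weighted logistic MLE via IRLS; returns the coefficient vector.

    Linear predictors are clipped at |eta| = 35 so separated fits saturate
    instead of overflowing; callers that must reject separation check the
    fitted probabilities themselves (see ``fit_propensity``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

    beta = np.zeros(p)
    # start intercept (first column assumed constant if present) at the logit of
    # the weighted mean for faster convergence
    ybar = float(np.average(y, weights=w))
    if 0 < ybar < 1 and np.all(X[:, 0] == 1.0):
        beta[0] = np.log(ybar / (1 - ybar))

    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = expit(eta)
        s = w * mu * (1 - mu)
        if np.all(s < 1e-12):
            break
        grad = X.T @ (w * (y - mu))
        H = (X * s[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def predict_logistic(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return expit(np.clip(np.asarray(X, dtype=float) @ beta, -35, 35))


def logistic_cov(X: np.ndarray, beta: np.ndarray, sample_weight=None) -> np.ndarray:
    """Inverse observed information of the (weighted) logistic fit."""
    X = np.asarray(X, dtype=float)
    mu = expit(X @ beta)
    w = np.ones(len(X)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    s = w * mu * (1 - mu)
    H = (X * s[:, None]).T @ X
    return np.linalg.inv(H)


def fit_poisson(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Log-link Poisson MLE via IRLS; returns the coefficient vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar > 0 and np.all(X[:, 0] == 1.0):
        beta[0] = np.log(ybar)
    for _ in range(max_iter):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def poisson_sandwich_cov(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Robust (HC0 sandwich) covariance for the Poisson fit — the standard
    variance for modified-Poisson risk-ratio regression on binary outcomes."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = np.exp(np.clip(X @ beta, -30, 30))
    bread = np.linalg.inv((X * mu[:, None]).T @ X)
    score = X * (y - mu)[:, None]
    meat = score.T @ score
    return bread @ meat @ bread
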