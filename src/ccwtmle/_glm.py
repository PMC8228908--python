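"""Weighted logistic regression by iteratively reweighted least squares.

A small, fast IRLS fitter used throughout the package: the GLM-family base
learners, the stepwise-AIC search and the per-replicate bootstrap refits all
need many weighted logistic fits (with optional offsets) on modest design
matrices, where the overhead of a full modelling framework dominates the
actual linear algebra.
"""

from __future__ import annotations

import numpy as np

# Linear predictors are clipped here before expit; keeps probabilities away
# from exact 0/1 under quasi-separation.
_ETA_MAX = 30.0


def expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_MAX, _ETA_MAX)))


def logit(p: np.ndarray | float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def fit_weighted_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    *,
    ridge: float = 1e-8,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fit logit P(y=1) = offset + X @ beta by weighted maximum likelihood.

    Parameters
    ----------
    X : (n, p) design matrix including any intercept column.
    y : (n,) binary response.
    weights : (n,) positive observation weights (case-control design weights
        times any frequency weights); defaults to 1.
    offset : (n,) fixed additive term on the logit scale.
    ridge : tiny L2 stabilizer on the coefficients, making the fit defined
        under separation; small enough to be irrelevant otherwise.

    Returns
    -------
    beta : (p,) coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = off + X @ beta
        mu = expit(eta)
        grad = X.T @ (w * (y - mu)) - ridge * beta
        s = w * mu * (1.0 - mu)
        hess = (X.T * s) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(grad)) < tol * max(1.0, w.sum()):
            break
    return beta


def weighted_deviance(
    y: np.ndarray, p: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """-2 * weighted Bernoulli log-likelihood (probabilities pre-clamped)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    return float(-2.0 * np.sum(w * (y * np.log(p) + (1.0 - y) * np.log1p(-p))))
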