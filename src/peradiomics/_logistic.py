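"""Minimal ridge-stabilized logistic regression with Wald statistics.

Used for univariate feature ranking and Wald-test importance, where a
closed-form standard error is needed and a small ridge penalty must keep
the fit finite under complete separation.
"""

from __future__ import annotations

import numpy as np


def logistic_fit(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit logit(p) = b0 + X b by penalized IRLS.

    Returns (coefficients incl. intercept, standard errors). The ridge
    penalty (not applied to the intercept) keeps separated data finite.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    pen = np.diag([0.0] + [ridge] * p)
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = design.T @ (y - mu) - pen @ beta
        hess = design.T @ (design * w[:, None]) + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    hess = design.T @ (design * w[:, None]) + pen
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return beta, se


def wald_z(x: np.ndarray, y: np.ndarray, ridge: float = 1e-4) -> float:
    """Wald z statistic of a single covariate in a univariate logistic fit."""
    beta, se = logistic_fit(np.asarray(x, float).reshape(-1, 1), y, ridge=ridge)
    return float(beta[1] / se[1])
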