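"""Light-weight logistic machinery for the permutation engine.

The permutation diagnostics re-test hundreds of re-scored variant subsets
against many phenotypes.  Refitting a full maximum-likelihood logistic
model per column is wasteful: under the null the covariate-only fit is
shared, and the Rao score test for an added column is closed-form given
that fit.  This module provides a plain Newton/IRLS logistic solver and a
vectorised score test over a matrix of candidate columns.  The reporting
fits elsewhere in the package go through statsmodels; agreement between
the two routes is covered by tests.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import FitError

_ETA_CLIP = 30.0


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS maximum-likelihood logistic fit.

    Returns ``(beta, cov, converged)`` where ``cov`` is the inverse
    observed information.  ``X`` must already include any intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix in logistic fit",
                           {"iteration": _, "beta": beta}) from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return beta, cov, converged


def score_test_columns(Z: np.ndarray, y: np.ndarray,
                       X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rao score test for each column of ``X`` added to the null model ``Z``.

    Fits the covariate-only logistic model once, then evaluates the
    efficient score statistic for every candidate column in a single pass.
    Returns ``(chi2, p, sign)`` arrays, one entry per column of ``X``.
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta0, _, _ = fit_logistic(Z, y)
    eta = np.clip(Z @ beta0, -_ETA_CLIP, _ETA_CLIP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    resid = y - mu

    U = X.T @ resid                                  # efficient scores
    WZ = Z * w[:, None]
    ZtWZ = Z.T @ WZ
    XtWZ = (X * w[:, None]).T @ Z                    # (B, p)
    # V_b = x_b' W x_b  -  x_b' W Z (Z' W Z)^-1 Z' W x_b
    solved = np.linalg.solve(ZtWZ, XtWZ.T)           # (p, B)
    V = np.einsum("ib,ib->b", X * w[:, None], X) - np.einsum(
        "bp,pb->b", XtWZ, solved)
    V = np.maximum(V, 1e-300)
    chi2 = U ** 2 / V
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p, np.sign(U)
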