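"""Cholesky-based generalized least squares with profiled scale.

Every model in this package reduces to ``x ~ MVN(X @ beta, sigma2 * V0)`` for
some structure matrix ``V0``; ``beta`` and ``sigma2`` always have closed-form
ML solutions given ``V0``.  These helpers centralize that computation.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

LOG2PI = float(np.log(2.0 * np.pi))


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def chol_lower(V0: np.ndarray, jitter: float = 0.0) -> np.ndarray:
    """Lower Cholesky factor, with one jittered retry on failure."""
    try:
        return linalg.cholesky(V0, lower=True)
    except linalg.LinAlgError:
        if jitter <= 0:
            jitter = 1e-10 * float(np.mean(np.diag(V0)))
        try:
            return linalg.cholesky(V0 + jitter * np.eye(V0.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise SingularCovarianceError("covariance structure is singular") from exc


def gls_profiled(X: np.ndarray, y: np.ndarray, V0: np.ndarray):
    """ML fit of ``y ~ MVN(X beta, sigma2 V0)`` with ``sigma2`` profiled out.

    Returns ``(loglik, beta, sigma2, aux)`` where ``aux`` carries the pieces
    needed for standard errors (whitened design, log|V0|, rss).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    L = chol_lower(V0)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        raise np.linalg.LinAlgError("zero residual variance")
    loglik = -0.5 * (n * (LOG2PI + np.log(sigma2)) + logdet + n)
    aux = {"Xw": Xw, "logdet_V0": logdet, "rss": rss, "L": L, "yw": yw}
    return float(loglik), np.atleast_1d(beta), float(sigma2), aux


def mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Log-density of a fully specified multivariate normal."""
    y = np.asarray(y, dtype=float)
    r = y - np.asarray(mean, dtype=float)
    L = chol_lower(np.asarray(cov, dtype=float))
    z = linalg.solve_triangular(L, r, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(-0.5 * (y.size * LOG2PI + logdet + z @ z))
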