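"""Phylogenetic generalized least squares with simultaneous Pagel's lambda."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._gls import gls_profiled
from .evo_models import lambda_transform
from .phylo_core import Phylogeny, vcv

__all__ = ["PglsFit", "fit_pgls", "pairwise_element_pgls"]


@dataclass(frozen=True)
class PglsFit:
    coef: np.ndarray  # intercept first
    se: np.ndarray
    t: np.ndarray
    p_values: np.ndarray
    names: tuple[str, ...]
    lam: float
    loglik: float
    n: int

    @property
    def slope(self) -> float:
        """First non-intercept coefficient (single-predictor convenience)."""
        return float(self.coef[1])

    @property
    def slope_p(self) -> float:
        return float(self.p_values[1])


def _as_matrix(tree: Phylogeny, data) -> np.ndarray:
    tips = tree.tip_labels
    if isinstance(data, dict):
        return np.array([float(data[lb]) for lb in tips])
    if isinstance(data, pd.Series):
        return data.loc[tips].to_numpy(dtype=float)
    x = np.asarray(data, dtype=float)
    if x.shape[0] != len(tips):
        raise ValueError("data length does not match tip count")
    return x


def fit_pgls(tree: Phylogeny, response, predictors, names=None, lam=None) -> PglsFit:
    """Regress ``response`` on one or more predictors with lambda-scaled
    phylogenetic residual covariance.

    lambda is estimated by bounded ML on [0, 1] (endpoints included: at 0 on
    a unit-depth tree the fit is ordinary least squares, at 1 it is BM-GLS),
    or fixed when ``lam`` is given.  Coefficient tests use t statistics on
    n - p degrees of freedom with the unbiased residual variance.
    """
    y = _as_matrix(tree, response)
    if isinstance(predictors, (dict, pd.Series)) or (
        isinstance(predictors, np.ndarray) and predictors.ndim == 1
    ):
        predictors = [predictors]
    if isinstance(predictors, pd.DataFrame):
        names = names or tuple(predictors.columns)
        predictors = [predictors[c] for c in predictors.columns]
    cols = [_as_matrix(tree, p) for p in predictors]
    n = y.size
    p = len(cols) + 1
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    X = np.column_stack([np.ones(n)] + cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear predictors: design is rank-deficient")
    C = vcv(tree)

    def loglik_at(lam: float) -> float:
        V0 = lambda_transform(C, lam).matrix
        ll, _, _, _ = gls_profiled(X, y, V0)
        return ll

    if lam is not None:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        best_lam = float(lam)
    else:
        res = optimize.minimize_scalar(
            lambda lm: -loglik_at(lm), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        best_lam, best_ll = float(res.x), -float(res.fun)
        for lm in (0.0, 1.0):
            ll = loglik_at(lm)
            if ll > best_ll:
                best_lam, best_ll = lm, ll

    V0 = lambda_transform(C, best_lam).matrix
    ll, beta, _, aux = gls_profiled(X, y, V0)
    df = n - p
    s2_unbiased = aux["rss"] / df
    XtX_inv = np.linalg.inv(aux["Xw"].T @ aux["Xw"])
    se = np.sqrt(s2_unbiased * np.diag(XtX_inv))
    t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    if names is None:
        names = tuple(f"x{i}" for i in range(1, len(cols) + 1))
    return PglsFit(
        coef=beta, se=se, t=t, p_values=pvals,
        names=("intercept", *names), lam=best_lam, loglik=ll, n=n,
    )


def pairwise_element_pgls(
    tree: Phylogeny, traits: pd.DataFrame, holm: bool = False
) -> dict[str, pd.DataFrame]:
    """Lower-triangular matrix of pairwise PGLS fits (row ~ column).

    ``traits`` is a species-indexed DataFrame of element columns.  No
    multiple-testing adjustment is applied unless ``holm=True``.
    """
    elements = list(traits.columns)
    if len(elements) < 2:
        raise ValueError("need at least 2 element columns")
    slopes = pd.DataFrame(np.nan, index=elements, columns=elements)
    pvals = pd.DataFrame(np.nan, index=elements, columns=elements)
    lams = pd.DataFrame(np.nan, index=elements, columns=elements)
    raw = []
    for i, row_el in enumerate(elements):
        for j in range(i):
            col_el = elements[j]
            fit = fit_pgls(tree, traits[row_el], traits[col_el], names=(col_el,))
            slopes.loc[row_el, col_el] = fit.slope
            pvals.loc[row_el, col_el] = fit.slope_p
            lams.loc[row_el, col_el] = fit.lam
            raw.append((row_el, col_el, fit.slope_p))
    if holm:
        order = sorted(range(len(raw)), key=lambda k: raw[k][2])
        m = len(raw)
        running = 0.0
        for rank, k in enumerate(order):
            r, c, pv = raw[k]
            adj = min(1.0, (m - rank) * pv)
            running = max(running, adj)
            pvals.loc[r, c] = running
    return {"slope": slopes, "p_value": pvals, "lambda": lams}
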