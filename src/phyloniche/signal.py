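"""Blomberg's K and its randomization test for phylogenetic signal."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .phylo_core import Phylogeny, vcv

__all__ = ["SignalResult", "blomberg_k", "k_permutation_test"]

#: refuse covariance matrices whose condition estimate exceeds this
MAX_CONDITION = 1e12


@dataclass(frozen=True)
class SignalResult:
    K: float
    p_value: float
    n_permutations: int
    observed_ratio: float
    expected_ratio: float


def _trait_vector(tree: Phylogeny, trait: dict[str, float]) -> np.ndarray:
    tips = tree.tip_labels
    extra = sorted(set(trait) - set(tips))
    missing = sorted(set(tips) - set(trait))
    if extra or missing:
        raise ValueError(
            f"trait/tip label mismatch: missing from trait {missing}, not in tree {extra}"
        )
    return np.array([float(trait[lb]) for lb in tips])


def _k_components(tree: Phylogeny):
    C = vcv(tree).matrix
    n = C.shape[0]
    if np.linalg.cond(C) > MAX_CONDITION:
        raise np.linalg.LinAlgError("phylogenetic covariance is near-singular")
    L = linalg.cholesky(C, lower=True)
    Linv_ones = linalg.solve_triangular(L, np.ones(n), lower=True)
    denom_1C1 = float(Linv_ones @ Linv_ones)  # 1' C^-1 1
    expected = (float(np.trace(C)) - n / denom_1C1) / (n - 1)
    return L, Linv_ones, denom_1C1, expected


def _k_from_columns(X: np.ndarray, L, Linv_ones, denom_1C1, expected) -> np.ndarray:
    """Blomberg's K for each column of X (vectorized over traits)."""
    n = X.shape[0]
    Xw = linalg.solve_triangular(L, X, lower=True)
    ahat = (Linv_ones @ Xw) / denom_1C1  # phylogenetic GLS mean per column
    R = X - ahat[None, :]
    mse0 = np.sum(R * R, axis=0) / (n - 1)
    Rw = Xw - np.outer(Linv_ones, ahat)
    mse = np.sum(Rw * Rw, axis=0) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: Phylogeny, trait: dict[str, float]) -> SignalResult:
    """Blomberg's K: observed vs Brownian-expected MSE0/MSE ratio.

    K = 1 indicates trait similarity exactly matching Brownian motion on the
    tree; K -> 0 indicates no phylogenetic structure.  The returned
    ``p_value`` is NaN (use :func:`k_permutation_test` for significance).
    """
    x = _trait_vector(tree, trait)
    if x.size < 3:
        raise ValueError("Blomberg's K requires at least 3 tips")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: trait is constant across tips")
    L, Linv_ones, denom, expected = _k_components(tree)
    k = float(_k_from_columns(x[:, None], L, Linv_ones, denom, expected)[0])
    obs = k * expected
    return SignalResult(
        K=k, p_value=float("nan"), n_permutations=0, observed_ratio=obs, expected_ratio=expected
    )


def k_permutation_test(
    tree: Phylogeny, trait: dict[str, float], n_perm: int = 999, seed=None
) -> SignalResult:
    """Randomization test of K against trait values shuffled across tips.

    p = (1 + #{K_perm >= K_obs}) / (n_perm + 1); ties count as extreme.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _trait_vector(tree, trait)
    if x.size < 3:
        raise ValueError("Blomberg's K requires at least 3 tips")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: trait is constant across tips")
    rng = np.random.default_rng(seed)
    L, Linv_ones, denom, expected = _k_components(tree)
    k_obs = float(_k_from_columns(x[:, None], L, Linv_ones, denom, expected)[0])

    perms = np.empty((x.size, n_perm))
    for b in range(n_perm):
        perms[:, b] = rng.permutation(x)
    k_perm = _k_from_columns(perms, L, Linv_ones, denom, expected)
    p = (1 + int(np.sum(k_perm >= k_obs - 1e-12))) / (n_perm + 1)
    return SignalResult(
        K=k_obs,
        p_value=float(p),
        n_permutations=n_perm,
        observed_ratio=k_obs * expected,
        expected_ratio=expected,
    )
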