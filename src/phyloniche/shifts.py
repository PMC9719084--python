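"""Detection of optimum shifts on a phylogeny under a single-alpha OU model.

A shift on an edge moves the optimum for the whole subtending clade, taking
effect at the parent end of the edge.  Shifted configurations are scored by a
penalized criterion and located by greedy forward search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _sla
from scipy import optimize

from ._gls import LOG2PI, chol_lower, gls_profiled
from .evo_models import ALPHA_BOUNDS, _ou_structure, _trait_vector, _validate
from .phylo_core import Phylogeny

__all__ = ["ShiftConfiguration", "shift_loglik", "search_shifts", "candidate_edges"]


@dataclass(frozen=True)
class ShiftConfiguration:
    """A fitted set of optimum shifts.

    ``shifts`` maps edge id (child node) -> optimum value on that edge's
    subtree; ``theta0`` is the background optimum at the root.
    """

    theta0: float
    shifts: dict[int, float]
    alpha: float
    sigma2: float
    loglik: float
    criterion: float
    edge_increments: dict[int, float] = field(default_factory=dict)
    trace: tuple = field(default_factory=tuple)

    @property
    def m(self) -> int:
        return len(self.shifts)


def candidate_edges(tree: Phylogeny) -> list[int]:
    """Edges (child-node ids) on which a shift is identifiable.

    Excludes any edge subtending every tip (its design column would be
    collinear with the intercept).
    """
    mask = tree.descendant_tip_mask()
    n = tree.n_tips
    return [int(v) for v in tree.preorder() if v != tree.root and mask[v].sum() < n]


def _design(tree: Phylogeny, edges: list[int], alpha: float) -> np.ndarray:
    """Intercept plus one column per shifted edge.

    A shift effective from depth t_e (the parent end of edge e) contributes
    1 - exp(-alpha (T - t_e)) to each tip descending through e.
    """
    T = tree.depth
    depths = tree.node_depths()
    mask = tree.descendant_tip_mask()
    X = np.ones((tree.n_tips, 1 + len(edges)))
    for j, e in enumerate(edges):
        t_e = depths[int(tree.parent[e])]
        X[:, 1 + j] = np.where(mask[e], -np.expm1(-alpha * (T - t_e)), 0.0)
    return X


def shift_loglik(tree: Phylogeny, trait, edges, alpha: float):
    """Log-likelihood of the shifted-OU model at a fixed alpha.

    Returns ``(loglik, thetas, sigma2)`` where ``thetas[0]`` is the base
    optimum and the rest are per-shift optimum increments.
    """
    x = _trait_vector(tree, trait)
    _validate(tree, x)
    tree.require_ultrametric()
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    edges = list(edges)
    valid = set(candidate_edges(tree))
    bad = [e for e in edges if e not in valid]
    if bad:
        raise ValueError(f"unidentifiable or invalid shift edges: {bad}")
    if len(set(edges)) != len(edges):
        raise ValueError("shift edges must be distinct")
    X = _design(tree, edges, alpha)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("unidentifiable configuration: rank-deficient design")
    loglik, beta, sigma2, _ = gls_profiled(X, x, _ou_structure(tree, alpha))
    return loglik, beta, sigma2


def _optimize_alpha(tree, x, edges, alpha_bounds, extra_candidates=()):
    lo, hi = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])

    def neg(z):
        a = float(np.exp(z))
        X = _design(tree, edges, a)
        try:
            loglik, _, _, _ = gls_profiled(X, x, _ou_structure(tree, a))
        except np.linalg.LinAlgError:
            return np.inf
        return -loglik

    best_z, best_f = lo, neg(lo)
    for a, b in zip(np.linspace(lo, hi, 4)[:-1], np.linspace(lo, hi, 4)[1:]):
        res = optimize.minimize_scalar(neg, bounds=(a, b), method="bounded")
        if res.fun < best_f:
            best_z, best_f = float(res.x), float(res.fun)
    for a in extra_candidates:
        z = float(np.log(a))
        f = neg(z)
        if f < best_f:
            best_z, best_f = z, f
    return float(np.exp(best_z)), -float(best_f)


def search_shifts(
    tree: Phylogeny,
    trait,
    max_shifts: int = 8,
    alpha_bounds=ALPHA_BOUNDS,
    penalty_per_shift: float | None = None,
) -> ShiftConfiguration:
    """Greedy forward search for optimum shifts under a penalized criterion.

    At each step the single edge giving the largest likelihood gain (at the
    current alpha) is proposed, alpha is re-optimized for the enlarged
    configuration, and the step is kept only if the criterion improves:

        criterion(m) = -2 lnL + (3 + m) ln n + 2 m ln E

    with E the number of candidate edges — a per-shift size cost plus a
    placement cost over the E possible locations.  ``penalty_per_shift``
    replaces the default per-shift charge ``ln n + 2 ln E`` when given
    (``np.inf`` forces m = 0).  The search is deterministic.
    """
    x = _trait_vector(tree, trait)
    _validate(tree, x)
    tree.require_ultrametric()
    cands = candidate_edges(tree)
    E = len(cands)
    if max_shifts >= E:
        raise ValueError(f"max_shifts={max_shifts} must be smaller than E={E} candidate edges")
    n = x.size

    def crit(loglik, m):
        if penalty_per_shift is not None:
            pen = (3.0 * np.log(n)) + m * penalty_per_shift
        else:
            pen = (3.0 + m) * np.log(n) + 2.0 * m * np.log(E)
        return -2.0 * loglik + pen

    edges: list[int] = []
    alpha, loglik = _optimize_alpha(tree, x, edges, alpha_bounds)
    score = crit(loglik, 0)
    trace = [(0, loglik, score)]
    mask = tree.descendant_tip_mask()

    while len(edges) < max_shifts:
        if penalty_per_shift is not None and np.isinf(penalty_per_shift):
            break
        # score all single-edge additions at the current alpha; the Cholesky
        # factor of the covariance is shared across candidates
        X0 = _design(tree, edges, alpha)
        V0 = _ou_structure(tree, alpha)
        L = chol_lower(V0)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Xw0 = _sla.solve_triangular(L, X0, lower=True)
        yw = _sla.solve_triangular(L, x, lower=True)
        Xall = _design(tree, [e for e in cands], alpha)[:, 1:]
        Xall_w = _sla.solve_triangular(L, Xall, lower=True)
        best_edge, best_ll = None, -np.inf
        seen_cols: set[bytes] = {mask[e].tobytes() for e in edges}
        for j, e in enumerate(cands):
            if e in edges:
                continue
            key = mask[e].tobytes()
            if key in seen_cols:
                continue  # identical descendant set -> collinear column
            Xw = np.column_stack([Xw0, Xall_w[:, j]])
            beta, res_arr, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            if rank < Xw.shape[1]:
                continue
            r = yw - Xw @ beta
            rss = float(r @ r)
            if rss <= 0:
                continue
            ll = -0.5 * (n * (LOG2PI + np.log(rss / n)) + logdet + n)
            if ll > best_ll:
                best_edge, best_ll = e, ll
        if best_edge is None:
            break
        new_edges = edges + [best_edge]
        new_alpha, new_ll = _optimize_alpha(
            tree, x, new_edges, alpha_bounds, extra_candidates=(alpha,)
        )
        new_score = crit(new_ll, len(new_edges))
        if new_score >= score:
            break
        edges, alpha, loglik, score = new_edges, new_alpha, new_ll, new_score
        trace.append((len(edges), loglik, score))

    ll, beta, sigma2 = shift_loglik(tree, x, edges, alpha)
    theta0 = float(beta[0])
    increments = {e: float(beta[1 + j]) for j, e in enumerate(edges)}
    # optimum on each shifted edge = theta0 + increments of all its ancestors + own
    optima = {}
    for e in edges:
        total = increments[e]
        v = int(tree.parent[e])
        while v != tree.root and v >= 0:
            if v in increments:
                total += increments[v]
            v = int(tree.parent[v])
        optima[e] = theta0 + total
    return ShiftConfiguration(
        theta0=theta0,
        shifts=optima,
        alpha=alpha,
        sigma2=sigma2,
        loglik=ll,
        criterion=score,
        edge_increments=increments,
        trace=tuple(trace),
    )
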