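"""Independent brute-force oracles used across the test suite.

Everything here works directly from the parent/length arrays by explicit
path walking and pairwise enumeration — deliberately *not* via the package's
covariance or design-matrix code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def root_path_edges(tree, node: int) -> list[int]:
    """Edges (child-node ids) on the path root -> node, in root-first order."""
    path = []
    v = int(node)
    while v != tree.root:
        path.append(v)
        v = int(tree.parent[v])
    return path[::-1]


def node_depth(tree, node: int) -> float:
    return float(sum(tree.length[e] for e in root_path_edges(tree, node)))


def shared_edges(tree, a: int, b: int) -> list[int]:
    pa, pb = root_path_edges(tree, a), root_path_edges(tree, b)
    out = []
    for x, y in zip(pa, pb):
        if x != y:
            break
        out.append(x)
    return out


def vcv_bruteforce(tree) -> np.ndarray:
    """BM covariance by pairwise shared-path enumeration."""
    tips = [int(t) for t in tree.tip_ids]
    n = len(tips)
    C = np.zeros((n, n))
    for i, j in itertools.product(range(n), range(n)):
        if i == j:
            C[i, j] = node_depth(tree, tips[i])
        else:
            C[i, j] = sum(tree.length[e] for e in shared_edges(tree, tips[i], tips[j]))
    return C


def regime_vcv_bruteforce(tree, painting) -> dict[str, np.ndarray]:
    tips = [int(t) for t in tree.tip_ids]
    n = len(tips)
    out = {r: np.zeros((n, n)) for r in painting.states}
    for i, j in itertools.product(range(n), range(n)):
        edges = (
            root_path_edges(tree, tips[i])
            if i == j
            else shared_edges(tree, tips[i], tips[j])
        )
        for e in edges:
            out[painting.edge_state[e]][i, j] += tree.length[e]
    return out


def ou_cov_bruteforce(tree, alpha: float, sigma2: float) -> np.ndarray:
    """Root-fixed OU covariance from per-pair shared/patristic path lengths."""
    tips = [int(t) for t in tree.tip_ids]
    n = len(tips)
    V = np.zeros((n, n))
    for i, j in itertools.product(range(n), range(n)):
        di, dj = node_depth(tree, tips[i]), node_depth(tree, tips[j])
        s = sum(tree.length[e] for e in shared_edges(tree, tips[i], tips[j])) if i != j else di
        d = di + dj - 2 * s
        V[i, j] = sigma2 / (2 * alpha) * np.exp(-alpha * d) * (1 - np.exp(-2 * alpha * s))
    return V


def oum_mean_bruteforce(tree, painting, alpha: float, theta: dict[str, float]) -> np.ndarray:
    """Hansen-model mean by per-segment integration along each root-to-tip path."""
    T = max(node_depth(tree, int(t)) for t in tree.tip_ids)
    means = []
    for t in tree.tip_ids:
        mu = theta[painting.root_state] * np.exp(-alpha * T)
        depth = 0.0
        for e in root_path_edges(tree, int(t)):
            t_b, t_e = depth, depth + float(tree.length[e])
            r = painting.edge_state[e]
            mu += theta[r] * (np.exp(-alpha * (T - t_e)) - np.exp(-alpha * (T - t_b)))
            depth = t_e
        means.append(mu)
    return np.array(means)


def shift_mean_bruteforce(tree, edges, alpha, theta0, deltas) -> np.ndarray:
    """Mean of the shifted-OU model: each shift acts from its parent-end depth."""
    T = max(node_depth(tree, int(t)) for t in tree.tip_ids)
    means = []
    for t in tree.tip_ids:
        path = set(root_path_edges(tree, int(t)))
        mu = theta0
        for e, d in zip(edges, deltas):
            if e in path:
                t_e = node_depth(tree, int(tree.parent[e]))
                mu += d * (1 - np.exp(-alpha * (T - t_e)))
        means.append(mu)
    return np.array(means)


def fitch_score_bruteforce(tree, tip_states: dict[str, str]) -> int:
    """Minimum number of edge state changes over all internal assignments."""
    states = sorted(set(tip_states.values()))
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    tip_nodes = [int(t) for t in tree.tip_ids]
    best = np.inf
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for t in tip_nodes:
            assign[t] = tip_states[tree.labels[t]]
        changes = sum(
            1
            for v in range(tree.n_nodes)
            if v != tree.root and assign[v] != assign[int(tree.parent[v])]
        )
        best = min(best, changes)
    return int(best)


def blomberg_k_bruteforce(tree, x: np.ndarray) -> float:
    """K from the explicit formula with a dense matrix inverse."""
    C = vcv_bruteforce(tree)
    n = x.size
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    ahat = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    r = x - ahat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected
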