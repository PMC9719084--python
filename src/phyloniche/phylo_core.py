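"""Rooted ultrametric phylogenies: parsing, validation, covariance, regimes, grafting.

The :class:`Phylogeny` is an immutable-by-convention array-backed tree.  Nodes
are integer ids ``0..n_nodes-1``; every node except the root has a parent and a
branch length.  Tip order is fixed at construction and is the row/column order
of every matrix derived from the tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "CovarianceMatrix",
    "RegimePainting",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "rescale_depth",
    "vcv",
    "graft_missing_taxa",
    "paint_regimes",
    "regime_vcv",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6
#: branch lengths of exactly zero (grafting artifacts) are nudged up to this
ZERO_LENGTH_NUDGE = 1e-9


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a Phylogeny invariant."""


@dataclass(frozen=True)
class CovarianceMatrix:
    """A symmetric tip-by-tip matrix with its label order."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("matrix order does not match label count")
        if not np.allclose(m, m.T, rtol=1e-10, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class RegimePainting:
    """Assignment of every edge (identified by its child node) to a regime.

    ``edge_state[child]`` is the state painted on the edge parent->child; the
    pendant edge of each tip always carries that tip's observed state.
    """

    edge_state: dict[int, str]
    root_state: str
    tip_states: dict[str, str]
    states: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.states:
            object.__setattr__(
                self, "states", tuple(sorted(set(self.edge_state.values()) | {self.root_state}))
            )

    @property
    def n_states(self) -> int:
        return len(self.states)


class Phylogeny:
    """Rooted tree with branch lengths, array-backed.

    Parameters
    ----------
    parent : sequence of int
        ``parent[i]`` is the parent node id of node ``i`` (-1 for the root).
    length : sequence of float
        Branch length of the edge above each node (0.0 for the root).
    labels : sequence of str or None
        Tip labels; ``None`` for internal nodes.
    """

    def __init__(self, parent, length, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if not (self.length.size == n and len(self.labels) == n):
            raise TreeValidationError("parent/length/labels arrays differ in size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeValidationError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self._cache: dict[str, np.ndarray] = {}
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                p = int(self.parent[i])
                if not 0 <= p < n:
                    raise TreeValidationError(f"node {i} has out-of-range parent {p}")
                self.children[p].append(i)
        self._check_connected_acyclic()
        self.tip_ids = np.array([i for i in range(n) if not self.children[i]], dtype=np.int64)
        tip_labels = [self.labels[i] for i in self.tip_ids]
        if any(lb is None for lb in tip_labels):
            raise TreeValidationError("every tip must be labeled")
        if len(set(tip_labels)) != len(tip_labels):
            dups = sorted({lb for lb in tip_labels if tip_labels.count(lb) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        nonroot = np.ones(n, dtype=bool)
        nonroot[self.root] = False
        if np.any(self.length[nonroot] < 0):
            raise TreeValidationError("negative branch lengths are not allowed")

    # -- construction ------------------------------------------------------

    def _check_connected_acyclic(self):
        n = self.parent.size
        seen = np.zeros(n, dtype=bool)
        order = self.preorder()
        seen[order] = True
        if not seen.all():
            raise TreeValidationError("tree is not connected")

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return read_newick(text)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.length.copy(), list(self.labels))

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def preorder(self) -> np.ndarray:
        """Node ids, parents before children."""
        key = "preorder"
        if key not in self._cache:
            order = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(reversed(self.children[v]))
            self._cache[key] = np.array(order, dtype=np.int64)
        return self._cache[key]

    def postorder(self) -> np.ndarray:
        key = "postorder"
        if key not in self._cache:
            self._cache[key] = self.preorder()[::-1].copy()
        return self._cache[key]

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        key = "depths"
        if key not in self._cache:
            d = np.zeros(self.n_nodes)
            for v in self.preorder():
                if v != self.root:
                    d[v] = d[self.parent[v]] + self.length[v]
            self._cache[key] = d
        return self._cache[key]

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.node_depths()[self.tip_ids].max())

    def is_ultrametric(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> bool:
        d = self.node_depths()[self.tip_ids]
        dmax = d.max()
        return bool(dmax > 0 and (dmax - d.min()) <= rtol * dmax)

    def require_ultrametric(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL):
        if not self.is_ultrametric(rtol):
            d = self.node_depths()[self.tip_ids]
            raise TreeValidationError(
                f"tree is not ultrametric (tip depths span [{d.min():.6g}, {d.max():.6g}])"
            )

    def mrca_node_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of MRCA node ids; diagonal is the tip itself."""
        key = "mrca"
        if key not in self._cache:
            n = self.n_tips
            tip_index = {int(t): i for i, t in enumerate(self.tip_ids)}
            M = np.empty((n, n), dtype=np.int64)
            tipsets: dict[int, np.ndarray] = {}
            for v in self.postorder():
                if not self.children[v]:
                    i = tip_index[int(v)]
                    M[i, i] = v
                    tipsets[v] = np.array([i], dtype=np.int64)
                else:
                    kids = [tipsets.pop(c) for c in self.children[v]]
                    for a in range(len(kids)):
                        for b in range(a + 1, len(kids)):
                            M[np.ix_(kids[a], kids[b])] = v
                            M[np.ix_(kids[b], kids[a])] = v
                    tipsets[v] = np.concatenate(kids)
            self._cache[key] = M
        return self._cache[key]

    def mrca_depth_matrix(self) -> np.ndarray:
        """Shared path length (depth of the MRCA) for every tip pair."""
        return self.node_depths()[self.mrca_node_matrix()]

    def patristic_matrix(self) -> np.ndarray:
        d = self.node_depths()[self.tip_ids]
        return d[:, None] + d[None, :] - 2.0 * self.mrca_depth_matrix()

    def descendant_tip_mask(self) -> np.ndarray:
        """(n_nodes, n_tips) boolean: tip j descends through node v (tips descend through themselves)."""
        key = "desc"
        if key not in self._cache:
            mask = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            tip_index = {int(t): i for i, t in enumerate(self.tip_ids)}
            for v in self.postorder():
                if not self.children[v]:
                    mask[v, tip_index[int(v)]] = True
                else:
                    for c in self.children[v]:
                        mask[v] |= mask[c]
            self._cache[key] = mask
        return self._cache[key]

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                s = self.labels[v]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v != self.root:
                s += f":{self.length[v]:.12g}"
            return s

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, self.n_nodes * 2 + 100))
        try:
            return fmt(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    def __repr__(self):
        return f"<Phylogeny {self.n_tips} tips, depth {self.depth:.6g}>"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on every non-root edge; duplicate tip labels
    and disconnected structures are rejected.  Polytomies are preserved.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        msg = str(exc)
        if "duplicate" in msg.lower() or "multiple times" in msg.lower():
            raise TreeValidationError(f"duplicate tip labels: {msg}") from None
        raise NewickParseError(f"malformed Newick: {msg}") from None

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent, length, labels = [], [], []
    for nd in nodes:
        if nd.parent_node is None:
            parent.append(-1)
            length.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            if nd.edge.length is None:
                raise TreeValidationError("missing branch length on a non-root edge")
            length.append(float(nd.edge.length))
        if nd.is_leaf():
            lb = nd.taxon.label if nd.taxon is not None else nd.label
            if lb is None:
                raise TreeValidationError("unlabeled tip")
            labels.append(str(lb))
        else:
            labels.append(None)
    return Phylogeny(parent, length, labels)


def rescale_depth(tree: Phylogeny, target: float = 1.0) -> Phylogeny:
    """Uniformly rescale branch lengths so the maximum tip depth equals ``target``."""
    if target <= 0:
        raise ValueError("target depth must be positive")
    depth = tree.depth
    if depth <= 0:
        raise TreeValidationError("cannot rescale a zero-depth tree")
    out = tree.copy()
    out.length = out.length * (target / depth)
    return out


def vcv(tree: Phylogeny) -> CovarianceMatrix:
    """Brownian-motion phylogenetic covariance: shared root-to-tip path lengths."""
    return CovarianceMatrix(tree.mrca_depth_matrix(), tuple(tree.tip_labels))


def graft_missing_taxa(tree: Phylogeny, placements, seed=None) -> Phylogeny:
    """Bind each new tip as sister to a randomly chosen anchor tip.

    ``placements`` is a sequence of ``(new_tip, anchor_tips)`` pairs (or a
    pandas DataFrame with columns ``new_tip`` and semicolon-separated
    ``anchor_tips``).  The attachment point is sampled uniformly along the
    chosen anchor's pendant edge and the new pendant length restores
    ultrametricity.  Deterministic given ``seed``.
    """
    placements = _normalize_placements(placements)
    if not placements:
        return tree.copy()
    tree.require_ultrametric()
    rng = np.random.default_rng(seed)
    T = tree.depth

    parent = list(tree.parent)
    length = list(tree.length)
    labels = list(tree.labels)

    def tip_id(label: str) -> int | None:
        try:
            i = labels.index(label)
        except ValueError:
            return None
        return i

    # validate all anchors up front so the error lists every missing label
    missing = sorted(
        {a for _, anchors in placements for a in anchors if tip_id(a) is None}
    )
    if missing:
        raise TreeValidationError(f"anchor tips absent from tree: {missing}")

    depths = {}

    def depth_of(i: int) -> float:
        if i not in depths:
            p = parent[i]
            depths[i] = 0.0 if p < 0 else depth_of(p) + length[i]
        return depths[i]

    for new_tip, anchors in placements:
        if not anchors:
            raise TreeValidationError(f"empty anchor set for {new_tip!r}")
        anchor = anchors[int(rng.integers(len(anchors)))]
        a = tip_id(anchor)
        if a is None:  # anchor could be a tip grafted earlier in this call
            raise TreeValidationError(f"anchor tips absent from tree: [{anchor!r}]")
        pend = length[a]
        attach = float(rng.uniform(0.0, pend))  # distance below the anchor's parent
        attach = min(max(attach, ZERO_LENGTH_NUDGE), pend - ZERO_LENGTH_NUDGE)
        p = parent[a]
        # new internal node splits the pendant edge of the anchor
        v = len(parent)
        parent.append(p)
        length.append(attach)
        labels.append(None)
        parent[a] = v
        length[a] = pend - attach
        # the new tip hangs from v down to depth T
        t = len(parent)
        parent.append(v)
        new_len = T - (depth_of(p) + attach)
        length.append(max(new_len, ZERO_LENGTH_NUDGE))
        labels.append(new_tip)
        depths.clear()

    return Phylogeny(parent, length, labels)


def _normalize_placements(placements) -> list[tuple[str, list[str]]]:
    if placements is None:
        return []
    if hasattr(placements, "iterrows"):  # DataFrame
        out = []
        for _, row in placements.iterrows():
            anchors = [a.strip() for a in str(row["anchor_tips"]).split(";") if a.strip()]
            out.append((str(row["new_tip"]), anchors))
        return out
    return [(str(t), list(a)) for t, a in placements]


def paint_regimes(tree: Phylogeny, tip_states: dict[str, str]) -> RegimePainting:
    """Assign a regime to every edge from tip states by Fitch parsimony.

    Bottom-up pass builds candidate sets (intersection when non-empty, else
    union); top-down pass resolves each node to its parent's state when
    possible, otherwise to the lexicographically first candidate.  Root
    ambiguity resolves to the majority tip state (ties broken
    lexicographically).  Each edge is painted with its child node's state, so
    pendant edges always match the tip states.
    """
    tips = tree.tip_labels
    missing = sorted(set(tips) - set(tip_states))
    if missing:
        raise TreeValidationError(f"missing tip states for: {missing}")

    candidate: dict[int, frozenset[str]] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            candidate[v] = frozenset({tip_states[tree.labels[v]]})
        else:
            sets = [candidate[c] for c in tree.children[v]]
            inter = frozenset.intersection(*sets)
            candidate[v] = inter if inter else frozenset.union(*sets)

    state: dict[int, str] = {}
    for v in tree.preorder():
        cand = candidate[v]
        if len(cand) == 1:
            state[v] = next(iter(cand))
        elif v == tree.root:
            counts: dict[str, int] = {}
            for lb in tips:
                s = tip_states[lb]
                if s in cand:
                    counts[s] = counts.get(s, 0) + 1
            if counts:
                best = max(counts.values())
                state[v] = min(s for s, c in counts.items() if c == best)
            else:
                state[v] = min(cand)
        else:
            ps = state[tree.parent[v]]
            state[v] = ps if ps in cand else min(cand)

    edge_state = {int(v): state[v] for v in tree.preorder() if v != tree.root}
    all_states = tuple(sorted(set(tip_states[lb] for lb in tips)))
    return RegimePainting(
        edge_state=edge_state,
        root_state=state[tree.root],
        tip_states={lb: tip_states[lb] for lb in tips},
        states=all_states,
    )


def fitch_score(painting: RegimePainting, tree: Phylogeny) -> int:
    """Number of state changes along edges implied by a painting."""
    changes = 0
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        ps = painting.root_state if p == tree.root else painting.edge_state[p]
        if painting.edge_state[int(v)] != ps:
            changes += 1
    return changes


def regime_vcv(tree: Phylogeny, painting: RegimePainting) -> dict[str, np.ndarray]:
    """Per-regime shared-path-length matrices.

    ``C_r[i, j]`` is the length of the shared root-to-MRCA path of tips *i*
    and *j* spent on edges painted with regime *r*; summing over regimes
    recovers the plain BM covariance.
    """
    M = tree.mrca_node_matrix()
    out = {}
    for r in painting.states:
        depth_r = np.zeros(tree.n_nodes)
        for v in tree.preorder():
            if v == tree.root:
                continue
            add = tree.length[v] if painting.edge_state[int(v)] == r else 0.0
            depth_r[v] = depth_r[tree.parent[v]] + add
        out[r] = depth_r[M]
    return out


def path_segments(tree: Phylogeny, painting: RegimePainting):
    """For each tip (in tip order), the root-to-tip edge segments.

    Returns a list of lists of ``(t_begin, t_end, regime)`` with depths
    measured from the root, ordered root -> tip.
    """
    depths = tree.node_depths()
    segs = []
    for t in tree.tip_ids:
        path = []
        v = int(t)
        while v != tree.root:
            p = int(tree.parent[v])
            path.append((float(depths[p]), float(depths[v]), painting.edge_state[v]))
            v = p
        segs.append(path[::-1])
    return segs


def prune_to_tips(tree: Phylogeny, keep: list[str]) -> Phylogeny:
    """Restrict the tree to the given tip labels, suppressing unary nodes."""
    keep_set = set(keep)
    missing = sorted(keep_set - set(tree.tip_labels))
    if missing:
        raise TreeValidationError(f"tips absent from tree: {missing}")
    keep_node = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.postorder():
        if not tree.children[v]:
            keep_node[v] = tree.labels[v] in keep_set
        else:
            keep_node[v] = any(keep_node[c] for c in tree.children[v])
    if not keep_node[tree.root]:
        raise TreeValidationError("no tips retained")

    parent, length, labels = [], [], []

    def build(v: int, acc_len: float, new_parent: int):
        kids = [c for c in tree.children[v] if keep_node[c]]
        if not tree.children[v] or len(kids) == 0:
            parent.append(new_parent)
            length.append(acc_len)
            labels.append(tree.labels[v])
            return
        if len(kids) == 1:
            # unary pass-through: accumulate length so depths are preserved
            c = kids[0]
            build(c, acc_len + float(tree.length[c]), new_parent)
            return
        me = len(parent)
        parent.append(new_parent)
        length.append(acc_len)
        labels.append(None)
        for c in kids:
            build(c, float(tree.length[c]), me)

    # the original root is always kept (even if unary) so that all
    # root-to-tip path lengths — and hence the covariance — are unchanged
    parent.append(-1)
    length.append(0.0)
    labels.append(None)
    for c in tree.children[tree.root]:
        if keep_node[c]:
            build(c, float(tree.length[c]), 0)
    return Phylogeny(parent, length, labels)
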