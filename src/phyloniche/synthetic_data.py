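"""Simulators with known ground truth for every model the pipeline fits.

Trait simulation is an exact multivariate-normal draw from the mean vector
and covariance matrix implied by the target model, so simulated data obey the
fitted likelihoods by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evo_models import (
    _ou_structure,
    delta_transform,
    oum_design_weights,
)
from .niche_descriptives import ELEMENTS, TraitTable
from .phylo_core import (
    Phylogeny,
    RegimePainting,
    paint_regimes,
    regime_vcv,
    rescale_depth,
    vcv,
)
from .shifts import _design as _shift_design

__all__ = [
    "SyntheticSpec",
    "simulate_tree",
    "simulate_regimes",
    "simulate_trait",
    "make_study_fixture",
]

MODELS = ("BM", "BMM", "DELTA", "OU1", "OUM", "SHIFT", "BM_PAIR")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating model, parameters, and mandatory seed for one simulation."""

    model: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    painting: RegimePainting | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for synthetic data")
        for key in ("sigma2", "alpha", "delta", "sigma2_noise"):
            if key in self.params and self.params[key] <= 0:
                raise ValueError(f"{key} must be positive")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _yule(n: int, rng: np.random.Generator):
    """Pure-birth tree (rate 1), unscaled.  Returns (parent, length, labels)."""
    # active lineages: (pending parent id, birth time); start from the root split
    parent: list[int] = [-1]
    length: list[float] = [0.0]
    labels: list = [None]
    active = [(0, 0.0), (0, 0.0)]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        p, birth = active.pop(i)
        v = len(parent)
        parent.append(p)
        length.append(t - birth)
        labels.append(None)
        active.append((v, t))
        active.append((v, t))
    T = t + rng.exponential(1.0 / len(active))
    for k, (p, birth) in enumerate(active):
        parent.append(p)
        length.append(T - birth)
        labels.append(f"t{k + 1}")
    return parent, length, labels


def simulate_tree(n: int, seed, rescale: bool = True) -> Phylogeny:
    """Simulate a Yule (pure-birth) tree with ``n`` tips, unit depth by default."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tree = Phylogeny(*_yule(n, rng))
    return rescale_depth(tree, 1.0) if rescale else tree


def simulate_regimes(tree: Phylogeny, method: str = "clade", params=None, seed=None):
    """Assign two regimes to the tips and paint the tree.

    ``clade`` gives the regime labelled second to the clade whose size is
    closest to ``fraction * n_tips`` (clean two-block structure); ``mk`` runs
    a symmetric 2-state Markov chain along branches at rate ``rate``.
    Returns ``(tip_states, painting)``.
    """
    params = dict(params or {})
    states = tuple(params.get("states", ("A", "B")))
    if len(states) != 2:
        raise ValueError("exactly two regime states required")
    tips = tree.tip_labels
    if method == "clade":
        frac = float(params.get("fraction", 0.5))
        target = frac * tree.n_tips
        mask = tree.descendant_tip_mask()
        best, best_err = None, np.inf
        for v in tree.preorder():
            if v == tree.root or not tree.children[v]:
                continue
            sz = int(mask[v].sum())
            if sz == tree.n_tips:
                continue
            err = abs(sz - target)
            if err < best_err:
                best, best_err = v, err
        in_clade = mask[best] if best is not None else np.zeros(tree.n_tips, bool)
        tip_states = {lb: states[1] if in_clade[i] else states[0] for i, lb in enumerate(tips)}
    elif method == "mk":
        rate = float(params.get("rate", 0.5))
        root_state = params.get("root_state", states[0])
        rng = np.random.default_rng(seed)
        node_state = {tree.root: root_state}
        flip = {states[0]: states[1], states[1]: states[0]}
        for v in tree.preorder():
            if v == tree.root:
                continue
            p_change = 0.5 * -np.expm1(-2.0 * rate * tree.length[v])
            s = node_state[int(tree.parent[v])]
            node_state[int(v)] = flip[s] if rng.random() < p_change else s
        tip_states = {tree.labels[int(t)]: node_state[int(t)] for t in tree.tip_ids}
    else:
        raise ValueError(f"unknown method {method!r}; use 'clade' or 'mk'")
    painting = paint_regimes(tree, tip_states)
    return tip_states, painting


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def model_mean_cov(tree: Phylogeny, spec: SyntheticSpec):
    """Mean vector and covariance matrix implied by the generating model."""
    p = spec.params
    n = tree.n_tips
    if spec.model == "BM":
        mean = np.full(n, p.get("root_state", 0.0))
        cov = p.get("sigma2", 1.0) * vcv(tree).matrix
    elif spec.model == "BMM":
        if spec.painting is None:
            raise ValueError("BMM simulation requires a regime painting")
        ra, rb = spec.painting.states
        Cr = regime_vcv(tree, spec.painting)
        cov = p[f"sigma2_{ra}"] * Cr[ra] + p[f"sigma2_{rb}"] * Cr[rb]
        mean = np.full(n, p.get("root_state", 0.0))
    elif spec.model == "DELTA":
        C = delta_transform(vcv(tree), p["delta"])
        cov = p.get("sigma2", 1.0) * C.matrix
        mean = np.full(n, p.get("root_state", 0.0))
    elif spec.model == "OU1":
        cov = p.get("sigma2", 1.0) * _ou_structure(tree, p["alpha"])
        mean = np.full(n, p.get("theta", 0.0))
    elif spec.model == "OUM":
        if spec.painting is None:
            raise ValueError("OUM simulation requires a regime painting")
        a = p["alpha"]
        W = oum_design_weights(tree, spec.painting, a)
        ra, rb = spec.painting.states
        theta = np.array([p[f"theta_{ra}"], p[f"theta_{rb}"]])
        mean = W @ theta
        cov = p.get("sigma2", 1.0) * _ou_structure(tree, a)
    elif spec.model == "SHIFT":
        a = p["alpha"]
        edges = list(p["edges"])
        X = _shift_design(tree, edges, a)
        beta = np.concatenate([[p.get("theta0", 0.0)], np.asarray(p["deltas"], float)])
        mean = X @ beta
        cov = p.get("sigma2", 1.0) * _ou_structure(tree, a)
    else:
        raise ValueError(f"model {spec.model!r} has no single-trait mean/cov")
    return mean, cov


def _mvn_draw(mean, cov, rng):
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    return mean + L @ rng.standard_normal(mean.size)


def simulate_trait(tree: Phylogeny, spec: SyntheticSpec):
    """Draw tip values under the spec's model; deterministic given the seed.

    Returns a ``{tip: value}`` map, or for ``BM_PAIR`` a pair of maps
    ``(x, y)`` with ``y = slope * x + independent BM noise``.
    """
    rng = np.random.default_rng(spec.seed)
    tips = tree.tip_labels
    if spec.model == "BM_PAIR":
        p = spec.params
        C = vcv(tree).matrix
        x = _mvn_draw(np.zeros(tree.n_tips), p.get("sigma2_x", 1.0) * C, rng)
        noise = _mvn_draw(np.zeros(tree.n_tips), p.get("sigma2_noise", 1.0) * C, rng)
        y = p.get("intercept", 0.0) + p.get("slope", 1.0) * x + noise
        return dict(zip(tips, x)), dict(zip(tips, y))
    mean, cov = model_mean_cov(tree, spec)
    x = _mvn_draw(mean, cov, rng)
    return dict(zip(tips, x))


# ---------------------------------------------------------------------------
# study-mimicking fixture
# ---------------------------------------------------------------------------

GROUP_SIZES = {"fern": 19, "herb": 16, "evergreen": 43, "deciduous": 24}

#: per-group mean concentrations (mg/g) used as log10 targets
GROUP_MEANS = {
    "fern": {"C": 396, "N": 22.44, "P": 1.69, "K": 16.09, "Ca": 6.58, "Mg": 2.23},
    "herb": {"C": 390, "N": 26.53, "P": 1.94, "K": 17.73, "Ca": 7.08, "Mg": 2.38},
    "evergreen": {"C": 433, "N": 19.16, "P": 1.30, "K": 9.08, "Ca": 8.49, "Mg": 3.73},
    "deciduous": {"C": 398, "N": 24.59, "P": 1.86, "K": 13.94, "Ca": 13.20, "Mg": 4.81},
}

#: log10-scale standard deviations per element
ELEMENT_SD = {"C": 0.02, "N": 0.08, "P": 0.11, "K": 0.13, "Ca": 0.30, "Mg": 0.16}

#: target inter-element correlations: N-P-K positive block, Ca-Mg strong,
#: C negative against the nutrients
ELEMENT_CORR = pd.DataFrame(
    [
        [1.00, -0.50, -0.45, -0.40, -0.10, -0.10],
        [-0.50, 1.00, 0.60, 0.50, 0.05, 0.05],
        [-0.45, 0.60, 1.00, 0.55, 0.10, 0.05],
        [-0.40, 0.50, 0.55, 1.00, 0.10, 0.15],
        [-0.10, 0.05, 0.10, 0.10, 1.00, 0.95],
        [-0.10, 0.05, 0.05, 0.15, 0.95, 1.00],
    ],
    index=list(ELEMENTS),
    columns=list(ELEMENTS),
)

#: share of species-level variance that follows the phylogeny
PHYLO_WEIGHT = 0.5


def _grouped_tree(seed) -> tuple[Phylogeny, dict[str, str]]:
    """102-tip unit-depth tree with one clean clade per life form."""
    rng = np.random.default_rng(seed)
    sub = {}
    for lf, size in GROUP_SIZES.items():
        t = simulate_tree(size, rng.integers(2**63), rescale=False)
        sub[lf] = rescale_depth(t, 0.5)

    parent, length, labels = [-1], [0.0], [None]

    def add_block(children_blocks, stem_to, stem_len):
        v = len(parent)
        parent.append(stem_to)
        length.append(stem_len)
        labels.append(None)
        return v

    def splice(tree: Phylogeny, below: int, prefix: str, life: dict):
        offset = len(parent)
        for i in range(tree.n_nodes):
            p = int(tree.parent[i])
            if p < 0:
                parent.append(below)
                length.append(0.25)
            else:
                parent.append(offset + p)
                length.append(float(tree.length[i]))
            lb = tree.labels[i]
            if lb is None:
                labels.append(None)
            else:
                name = f"{prefix}_{lb}"
                labels.append(name)
                life[name] = prefix

    life: dict[str, str] = {}
    herb_node = add_block(None, 0, 0.25)
    woody_node = add_block(None, 0, 0.25)
    splice(sub["fern"], herb_node, "fern", life)
    splice(sub["herb"], herb_node, "herb", life)
    splice(sub["evergreen"], woody_node, "evergreen", life)
    splice(sub["deciduous"], woody_node, "deciduous", life)
    return Phylogeny(parent, length, labels), life


def make_study_fixture(seed):
    """102-species fixture: clade-structured tree plus a six-element table.

    Life-form clades of sizes 19/16/43/24 (fern/herb/evergreen/deciduous);
    log10 concentrations drawn matrix-normally with phylogenetically
    structured rows and the target inter-element correlations, centered on
    the per-group mean concentrations.  Returns
    ``(tree, trait_table, ground_truth)``.
    """
    rng = np.random.default_rng(seed)
    tree, life = _grouped_tree(rng.integers(2**63))
    species = tree.tip_labels
    n = len(species)

    mean_log = np.array(
        [[np.log10(GROUP_MEANS[life[sp]][el]) for el in ELEMENTS] for sp in species]
    )
    sd = np.array([ELEMENT_SD[el] for el in ELEMENTS])
    sigma = ELEMENT_CORR.to_numpy() * np.outer(sd, sd)
    row_cov = PHYLO_WEIGHT * vcv(tree).matrix + (1 - PHYLO_WEIGHT) * np.eye(n)
    A = np.linalg.cholesky(row_cov + 1e-12 * np.eye(n))
    B = np.linalg.cholesky(sigma + 1e-12 * np.eye(len(ELEMENTS)))
    Z = rng.standard_normal((n, len(ELEMENTS)))
    log_conc = mean_log + A @ Z @ B.T

    df = pd.DataFrame(10.0**log_conc, index=pd.Index(species, name="species"), columns=list(ELEMENTS))
    df["life_form"] = [life[sp] for sp in species]
    table = TraitTable(df)
    truth = {
        "seed": seed,
        "group_sizes": dict(GROUP_SIZES),
        "group_means_mg_per_g": {g: dict(m) for g, m in GROUP_MEANS.items()},
        "log10_sd": dict(ELEMENT_SD),
        "element_correlation": ELEMENT_CORR.to_numpy().tolist(),
        "phylo_weight": PHYLO_WEIGHT,
    }
    return tree, table, truth
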