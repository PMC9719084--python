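"""ML fitting and AICc comparison of continuous trait-evolution models.

Five candidate models are supported:

* ``BM``    — single-rate Brownian motion (closed-form ML).
* ``BMM``   — Brownian motion with one rate per regime (two regimes).
* ``DELTA`` — node-depth power transform of the BM covariance.
* ``OU1``   — Ornstein-Uhlenbeck with a single optimum, root fixed at it.
* ``OUM``   — OU with one optimum per regime (Hansen model), single alpha
  and rate, root fixed at the root-regime optimum.

All fits profile the mean parameters and the scale ``sigma2`` analytically
(GLS) and reduce to at most a one-dimensional bounded likelihood search,
run from several log-spaced starting points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._gls import gls_profiled
from .phylo_core import (
    CovarianceMatrix,
    Phylogeny,
    RegimePainting,
    path_segments,
    regime_vcv,
    vcv,
)

__all__ = [
    "ModelFit",
    "ModelComparison",
    "fit_bm",
    "fit_bmm",
    "fit_delta",
    "fit_ou1",
    "fit_oum",
    "delta_transform",
    "lambda_transform",
    "ou_covariance",
    "oum_design_weights",
    "aicc",
    "compare_models",
]

ALPHA_BOUNDS = (1e-4, 1e3)
DELTA_BOUNDS = (1e-3, 500.0)
RATE_RATIO_BOUNDS = (1e-6, 1e6)
N_RESTARTS = 5
_K_PER_MODEL = {"BM": 2, "BMM": 3, "DELTA": 3, "OU1": 3, "OUM": 4}


@dataclass(frozen=True)
class ModelFit:
    model: str
    loglik: float
    params: dict[str, float]
    k: int
    n: int
    aicc: float
    converged: bool = True
    at_boundary: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in _K_PER_MODEL:
            raise ValueError(f"unknown model {self.model!r}")
        if self.k != _K_PER_MODEL[self.model]:
            raise ValueError(f"{self.model} must have k={_K_PER_MODEL[self.model]}")


@dataclass(frozen=True)
class ModelComparison:
    fits: tuple[ModelFit, ...]
    delta_aicc: tuple[float, ...]
    best: ModelFit
    equivalent: tuple[ModelFit, ...]


# ---------------------------------------------------------------------------
# covariance transforms
# ---------------------------------------------------------------------------


def delta_transform(C: CovarianceMatrix, delta: float) -> CovarianceMatrix:
    """Pagel's delta: elementwise power of shared path lengths (unit-depth tree).

    delta > 1 concentrates change late in the tree, delta < 1 early.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not np.allclose(np.diag(C.matrix), 1.0, rtol=1e-6):
        raise ValueError("delta transform requires a unit-depth ultrametric tree")
    if delta == 1.0:
        return C
    return CovarianceMatrix(np.power(C.matrix, delta), C.labels)


def lambda_transform(C: CovarianceMatrix, lam: float) -> CovarianceMatrix:
    """Pagel's lambda: multiply off-diagonal covariances, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if lam == 1.0:
        return C
    m = lam * C.matrix
    np.fill_diagonal(m, np.diag(C.matrix))
    return CovarianceMatrix(m, C.labels)


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float) -> CovarianceMatrix:
    """OU covariance on an ultrametric tree with the root fixed at the optimum.

    V(i,j) = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij))
    with s_ij the MRCA depth and d_ij the patristic distance.
    """
    if alpha <= 0 or sigma2 <= 0:
        raise ValueError("alpha and sigma2 must be positive")
    tree.require_ultrametric()
    return CovarianceMatrix(sigma2 * _ou_structure(tree, alpha), tuple(tree.tip_labels))


def _ou_structure(tree: Phylogeny, alpha: float) -> np.ndarray:
    S = tree.mrca_depth_matrix()
    D = tree.patristic_matrix()
    return np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)


def oum_design_weights(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> np.ndarray:
    """Hansen-model regime weights (tips x regimes), rows summing to one.

    A lineage segment in regime r spanning depths (t_b, t_e] contributes
    exp(-alpha (T - t_e)) - exp(-alpha (T - t_b)); the residual root weight
    exp(-alpha T) goes to the root regime.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    tree.require_ultrametric()
    T = tree.depth
    regimes = list(painting.states)
    ridx = {r: j for j, r in enumerate(regimes)}
    W = np.zeros((tree.n_tips, len(regimes)))
    for i, segs in enumerate(path_segments(tree, painting)):
        for t_b, t_e, r in segs:
            W[i, ridx[r]] += np.exp(-alpha * (T - t_e)) - np.exp(-alpha * (T - t_b))
        W[i, ridx[painting.root_state]] += np.exp(-alpha * T)
    return W


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def compare_models(fits: list[ModelFit]) -> ModelComparison:
    """Rank fits by AICc; models within 2 units of the best are equivalent.

    Ties break toward fewer parameters, then declaration order.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on different sample sizes: {sorted(ns)}")
    amin = min(f.aicc for f in fits)
    deltas = tuple(f.aicc - amin for f in fits)
    best = min(enumerate(fits), key=lambda t: (t[1].aicc, t[1].k, t[0]))[1]
    equiv = tuple(f for f, d in zip(fits, deltas) if d < 2.0)
    return ModelComparison(fits=tuple(fits), delta_aicc=deltas, best=best, equivalent=equiv)


# ---------------------------------------------------------------------------
# likelihood evaluators at explicit parameters (shared with tests/simulators)
# ---------------------------------------------------------------------------


def _trait_vector(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, dict):
        tips = tree.tip_labels
        missing = sorted(set(tips) - set(trait))
        extra = sorted(set(trait) - set(tips))
        if missing or extra:
            raise ValueError(
                f"trait/tip mismatch: missing {missing}, unknown {extra}"
            )
        return np.array([float(trait[lb]) for lb in tips])
    x = np.asarray(trait, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("trait vector length does not match tip count")
    return x


def _validate(tree: Phylogeny, x: np.ndarray):
    if x.size < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant across tips")


def _maximize_scalar(f, log_bounds, n_restarts=N_RESTARTS):
    """Maximize f over a log-scaled bounded scalar.

    A log-spaced grid scan (2 points per restart plus endpoints) locates the
    basin; a single bounded search refines within the bracketing interval.
    """
    lo, hi = log_bounds
    grid = np.linspace(lo, hi, 2 * n_restarts + 3)
    vals = np.array([f(z) for z in grid])
    i = int(np.nanargmax(vals))
    best_x, best_val = float(grid[i]), float(vals[i])
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda z: -f(z), bounds=(a, b), method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > best_val:
            best_val, best_x = -float(res.fun), float(res.x)
    return best_x, best_val


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


def fit_bm(tree: Phylogeny, trait) -> ModelFit:
    """Single-rate Brownian motion; mean and rate have closed-form ML solutions."""
    x = _trait_vector(tree, trait)
    _validate(tree, x)
    C = vcv(tree).matrix
    n = x.size
    ones = np.ones((n, 1))
    loglik, beta, sigma2, _ = gls_profiled(ones, x, C)
    params = {"sigma2": sigma2, "root_state": float(beta[0])}
    return ModelFit("BM", loglik, params, k=2, n=n, aicc=aicc(loglik, 2, n))


def fit_bmm(tree: Phylogeny, trait, painting: RegimePainting) -> ModelFit:
    """Two-rate Brownian motion with regime-specific rates.

    V = sigma2_a * C_a + sigma2_b * C_b, optimized over the log rate ratio
    with the first rate and mean profiled.  Reduces exactly to BM when the
    ratio is one, so lnL(BMM) >= lnL(BM) is guaranteed.
    """
    x = _trait_vector(tree, trait)
    _validate(tree, x)
    if len(painting.states) != 2:
        raise ValueError(
            f"BMM requires exactly 2 regimes, got {len(painting.states)}; use fit_bm for one"
        )
    Cr = regime_vcv(tree, painting)
    ra, rb = painting.states
    Ca, Cb = Cr[ra], Cr[rb]
    for lab, M in ((ra, Ca), (rb, Cb)):
        if float(np.trace(M)) <= 0:
            raise ValueError(f"regime {lab!r} occupies zero branch length")
    n = x.size
    ones = np.ones((n, 1))

    def profile(log_ratio: float) -> float:
        ratio = np.exp(log_ratio)
        loglik, _, _, _ = gls_profiled(ones, x, Ca + ratio * Cb)
        return loglik

    log_bounds = tuple(np.log(RATE_RATIO_BOUNDS))
    z, loglik = _maximize_scalar(profile, log_bounds)
    if profile(0.0) > loglik:  # ratio 1 reduces to BM: guarantees nesting
        z = 0.0
    ratio = float(np.exp(z))
    loglik_fit, beta, s, _ = gls_profiled(ones, x, Ca + ratio * Cb)
    params = {
        f"sigma2_{ra}": s,
        f"sigma2_{rb}": s * ratio,
        "root_state": float(beta[0]),
    }
    at_bound = min(abs(z - log_bounds[0]), abs(z - log_bounds[1])) < 1e-6
    return ModelFit(
        "BMM", loglik_fit, params, k=3, n=n, aicc=aicc(loglik_fit, 3, n),
        at_boundary=at_bound, diagnostics={"rate_ratio": ratio, "regimes": (ra, rb)},
    )


def fit_delta(tree: Phylogeny, trait, delta_bounds=DELTA_BOUNDS) -> ModelFit:
    """Pagel's delta by bounded 1-D ML, with a likelihood-ratio test vs delta=1.

    The upper bound defaults to 500 (well past common library defaults)
    because strongly tip-concentrated change yields very large estimates.
    """
    x = _trait_vector(tree, trait)
    _validate(tree, x)
    tree.require_ultrametric()
    C = vcv(tree)
    if abs(tree.depth - 1.0) > 1e-6:
        raise ValueError("delta fit requires a unit-depth tree (rescale first)")
    n = x.size
    ones = np.ones((n, 1))

    def profile(log_delta: float) -> float:
        d = np.exp(log_delta)
        loglik, _, _, _ = gls_profiled(ones, x, delta_transform(C, d).matrix)
        return loglik

    log_bounds = (np.log(delta_bounds[0]), np.log(delta_bounds[1]))
    z, _ = _maximize_scalar(profile, log_bounds)
    # guarantee nesting: the BM point delta=1 is always a candidate
    if profile(0.0) > profile(z):
        z = 0.0
    delta_hat = float(np.exp(z))
    loglik, beta, s, _ = gls_profiled(ones, x, delta_transform(C, delta_hat).matrix)
    loglik_bm = fit_bm(tree, x).loglik
    lrt = max(0.0, 2.0 * (loglik - loglik_bm))
    p_lrt = float(stats.chi2.sf(lrt, df=1))
    at_bound = min(abs(z - log_bounds[0]), abs(z - log_bounds[1])) < 1e-6
    params = {"delta": delta_hat, "sigma2": s, "root_state": float(beta[0])}
    return ModelFit(
        "DELTA", loglik, params, k=3, n=n, aicc=aicc(loglik, 3, n),
        at_boundary=at_bound,
        diagnostics={"lrt_stat": lrt, "lrt_p_value": p_lrt, "null_loglik": loglik_bm},
    )


def fit_ou1(tree: Phylogeny, trait, alpha_bounds=ALPHA_BOUNDS) -> ModelFit:
    """Single-optimum OU with the root state fixed at the optimum.

    The mean is theta * 1; theta and sigma2 are profiled, alpha is found by
    bounded 1-D search on the log scale.
    """
    x = _trait_vector(tree, trait)
    _validate(tree, x)
    tree.require_ultrametric()
    n = x.size
    ones = np.ones((n, 1))

    def profile(log_alpha: float) -> float:
        loglik, _, _, _ = gls_profiled(ones, x, _ou_structure(tree, np.exp(log_alpha)))
        return loglik

    log_bounds = (np.log(alpha_bounds[0]), np.log(alpha_bounds[1]))
    z, _ = _maximize_scalar(profile, log_bounds)
    alpha = float(np.exp(z))
    loglik, beta, s, _ = gls_profiled(ones, x, _ou_structure(tree, alpha))
    at_bound = min(abs(z - log_bounds[0]), abs(z - log_bounds[1])) < 1e-6
    params = {"alpha": alpha, "sigma2": s, "optimum": float(beta[0])}
    return ModelFit(
        "OU1", loglik, params, k=3, n=n, aicc=aicc(loglik, 3, n), at_boundary=at_bound
    )


def fit_oum(
    tree: Phylogeny, trait, painting: RegimePainting, alpha_bounds=ALPHA_BOUNDS
) -> ModelFit:
    """Two-optimum Hansen OU model (single alpha and rate, root at root-regime optimum).

    The OU1 mean space is contained in the OUM design (weight rows sum to
    one), so lnL(OUM) >= lnL(OU1) holds at the optimum.
    """
    x = _trait_vector(tree, trait)
    _validate(tree, x)
    tree.require_ultrametric()
    if len(painting.states) != 2:
        raise ValueError(f"OUM requires exactly 2 regimes, got {len(painting.states)}")
    n = x.size

    def profile(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        W = oum_design_weights(tree, painting, a)
        try:
            loglik, _, _, _ = gls_profiled(W, x, _ou_structure(tree, a))
        except np.linalg.LinAlgError:
            return -np.inf
        return loglik

    log_bounds = (np.log(alpha_bounds[0]), np.log(alpha_bounds[1]))
    z, _ = _maximize_scalar(profile, log_bounds)
    # guarantee nesting against OU1 at its own alpha-hat
    ou1 = fit_ou1(tree, x, alpha_bounds)
    z_ou1 = np.log(ou1.params["alpha"])
    if profile(z_ou1) > profile(z):
        z = float(z_ou1)
    alpha = float(np.exp(z))
    W = oum_design_weights(tree, painting, alpha)
    loglik, beta, s, _ = gls_profiled(W, x, _ou_structure(tree, alpha))
    ra, rb = painting.states
    at_bound = min(abs(z - log_bounds[0]), abs(z - log_bounds[1])) < 1e-6
    params = {
        "alpha": alpha,
        "sigma2": s,
        f"optimum_{ra}": float(beta[0]),
        f"optimum_{rb}": float(beta[1]),
    }
    return ModelFit(
        "OUM", loglik, params, k=4, n=n, aicc=aicc(loglik, 4, n),
        at_boundary=at_bound, diagnostics={"regimes": (ra, rb)},
    )
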