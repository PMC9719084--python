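"""End-to-end orchestration: descriptives, signal, model fits, shifts, PGLS.

:func:`run_full_analysis` reproduces the whole workflow on one tree/table
pair; :func:`tree_uncertainty_replicates` repeats the signal tests over many
randomly grafted trees to measure verdict stability.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import evo_models, pgls, shifts, signal
from .niche_descriptives import TraitTable, fold_ranges, pca_scores, summarize_groups
from .phylo_core import (
    Phylogeny,
    graft_missing_taxa,
    paint_regimes,
    prune_to_tips,
    rescale_depth,
)

log = logging.getLogger("phyloniche")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "tree_uncertainty_replicates"]


@dataclass
class AnalysisConfig:
    n_permutations: int = 999
    seed: int = 0
    pca_scale: str = "correlation"
    pca_log10: bool = True
    max_shifts: int = 8
    shift_penalty: float | None = None
    alpha_bounds: tuple[float, float] = evo_models.ALPHA_BOUNDS
    delta_bounds: tuple[float, float] = evo_models.DELTA_BOUNDS
    holm: bool = False
    run_shifts: bool = True


@dataclass
class AnalysisReport:
    signal: dict = field(default_factory=dict)
    model_comparison: dict = field(default_factory=dict)
    shift_configurations: dict = field(default_factory=dict)
    pgls_matrix: dict = field(default_factory=dict)
    descriptives: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def to_json(self, path=None, indent=2):
        payload = json.dumps(asdict(self), indent=indent, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return str(obj)


def _fit_dict(fit: evo_models.ModelFit, backtransform: bool) -> dict:
    d = {
        "model": fit.model,
        "loglik": fit.loglik,
        "aicc": fit.aicc,
        "k": fit.k,
        "params": dict(fit.params),
        "at_boundary": fit.at_boundary,
        "diagnostics": {k: v for k, v in fit.diagnostics.items() if np.isscalar(v)},
    }
    if backtransform:
        # optima were fitted on log10 concentrations; also report mg/g
        bt = {
            f"{k}_mg_per_g": float(10.0**v)
            for k, v in fit.params.items()
            if k.startswith("optimum")
        }
        d["params_backtransformed"] = bt
    return d


def prepare_inputs(tree: Phylogeny, table: TraitTable):
    """Match tree and table, prune extra tips, rescale depth to one."""
    tips = set(tree.tip_labels)
    species = set(table.species)
    overlap = tips & species
    if len(overlap) < 3:
        raise ValueError(f"only {len(overlap)} species shared between tree and table")
    dropped_tips = sorted(tips - species)
    if dropped_tips:
        warnings.warn(f"pruning {len(dropped_tips)} tree tips absent from the trait table")
        tree = prune_to_tips(tree, sorted(overlap))
    dropped_species = sorted(species - tips)
    if dropped_species:
        warnings.warn(f"dropping {len(dropped_species)} species absent from the tree")
        table = TraitTable(table.data.loc[sorted(overlap)])
    return rescale_depth(tree, 1.0), table


def run_full_analysis(
    tree: Phylogeny, table: TraitTable, config: AnalysisConfig | None = None
) -> AnalysisReport:
    """Run the complete comparative workflow on one tree and trait table.

    Stages that fail are recorded in ``report.failures`` and the run
    continues.  Deterministic given ``config.seed``.
    """
    config = config or AnalysisConfig()
    report = AnalysisReport()
    t0 = time.time()
    tree, table = prepare_inputs(tree, table)
    logx = table.log10()
    variables: dict[str, dict[str, float]] = {
        el: logx[el].to_dict() for el in table.elements
    }

    # descriptives + PCA scores (PC1/PC2 join the analyzed variables)
    scores = None
    try:
        pca = pca_scores(table, scale=config.pca_scale, log10=config.pca_log10)
        scores = pca.scores[["PC1", "PC2"]] if pca.scores.shape[1] >= 2 else None
        groups = {}
        for grouping in ("herbaceous/woody", "evergreen/deciduous", "fern/herb"):
            try:
                groups[grouping] = summarize_groups(table, grouping, extra_columns=scores)
            except ValueError as exc:
                report.failures[f"descriptives:{grouping}"] = str(exc)
        report.descriptives = {
            "group_summaries": {k: v.to_dict(orient="records") for k, v in groups.items()},
            "pca": {
                "explained_percent": (100 * pca.explained).tolist(),
                "pc1_pc2_percent": pca.pc1_pc2_percent,
                "loadings": pca.loadings.to_dict(),
            },
            "fold_ranges": fold_ranges(table).to_dict(),
        }
        if scores is not None:
            for pc in ("PC1", "PC2"):
                variables[pc] = scores[pc].to_dict()
    except (ValueError, np.linalg.LinAlgError) as exc:
        report.failures["descriptives"] = str(exc)

    painting = paint_regimes(
        tree, table.coarse_life_form().to_dict()
    ) if len(set(table.coarse_life_form())) == 2 else None

    rng = np.random.default_rng(config.seed)
    for name, trait in variables.items():
        sub_seed = int(rng.integers(2**63))
        try:
            res = signal.k_permutation_test(
                tree, trait, n_perm=config.n_permutations, seed=sub_seed
            )
            report.signal[name] = {
                "K": res.K,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "significant": res.p_value < 0.05,
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            report.failures[f"signal:{name}"] = str(exc)

        try:
            is_element = name not in ("PC1", "PC2")
            fits = [
                evo_models.fit_bm(tree, trait),
                evo_models.fit_delta(tree, trait, config.delta_bounds),
                evo_models.fit_ou1(tree, trait, config.alpha_bounds),
            ]
            if painting is not None:
                fits.insert(1, evo_models.fit_bmm(tree, trait, painting))
                fits.append(evo_models.fit_oum(tree, trait, painting, config.alpha_bounds))
            comp = evo_models.compare_models(fits)
            report.model_comparison[name] = {
                "fits": [_fit_dict(f, backtransform=is_element) for f in comp.fits],
                "delta_aicc": list(comp.delta_aicc),
                "best": comp.best.model,
                "equivalent": [f.model for f in comp.equivalent],
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            report.failures[f"models:{name}"] = str(exc)

        if config.run_shifts:
            try:
                cfg = shifts.search_shifts(
                    tree,
                    trait,
                    max_shifts=config.max_shifts,
                    alpha_bounds=config.alpha_bounds,
                    penalty_per_shift=config.shift_penalty,
                )
                report.shift_configurations[name] = {
                    "n_shifts": cfg.m,
                    "theta0": cfg.theta0,
                    "alpha": cfg.alpha,
                    "sigma2": cfg.sigma2,
                    "loglik": cfg.loglik,
                    "criterion": cfg.criterion,
                    "shifts": {
                        str(e): {
                            "optimum": v,
                            "tips": [
                                tree.tip_labels[i]
                                for i in np.flatnonzero(tree.descendant_tip_mask()[e])
                            ],
                        }
                        for e, v in cfg.shifts.items()
                    },
                }
            except (ValueError, np.linalg.LinAlgError) as exc:
                report.failures[f"shifts:{name}"] = str(exc)

    try:
        if len(table.elements) >= 2:
            mats = pgls.pairwise_element_pgls(tree, logx, holm=config.holm)
            report.pgls_matrix = {k: v.to_dict() for k, v in mats.items()}
    except (ValueError, np.linalg.LinAlgError) as exc:
        report.failures["pgls"] = str(exc)

    report.metadata = {
        "n_species": table.n,
        "elements": list(table.elements),
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "runtime_s": round(time.time() - t0, 2),
        "config": asdict(config),
    }
    return report


def write_tables(report: AnalysisReport, out_dir) -> list[str]:
    """Write the report's tabular sections as TSV files; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []

    def emit(name: str, df: pd.DataFrame):
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t")
        written.append(path)

    if report.signal:
        emit("signal", pd.DataFrame(report.signal).T.rename_axis("variable"))
    if report.model_comparison:
        rows = []
        for var, comp in report.model_comparison.items():
            for f, d in zip(comp["fits"], comp["delta_aicc"]):
                rows.append(
                    {
                        "variable": var,
                        "model": f["model"],
                        "loglik": f["loglik"],
                        "aicc": f["aicc"],
                        "delta_aicc": d,
                        "best": f["model"] == comp["best"],
                        **{f"param_{k}": v for k, v in f["params"].items()},
                    }
                )
        emit("model_comparison", pd.DataFrame(rows).set_index("variable"))
    if report.pgls_matrix:
        for key, mat in report.pgls_matrix.items():
            emit(f"pgls_{key}", pd.DataFrame(mat))
    if report.descriptives.get("group_summaries"):
        frames = []
        for grouping, recs in report.descriptives["group_summaries"].items():
            df = pd.DataFrame(recs)
            df.insert(0, "grouping", grouping)
            frames.append(df)
        emit("group_summaries", pd.concat(frames).set_index("grouping"))
    if report.shift_configurations:
        rows = []
        for var, cfg in report.shift_configurations.items():
            rows.append(
                {
                    "variable": var,
                    "n_shifts": cfg["n_shifts"],
                    "theta0": cfg["theta0"],
                    "alpha": cfg["alpha"],
                    "criterion": cfg["criterion"],
                    "shift_edges": ";".join(cfg["shifts"]),
                }
            )
        emit("shifts", pd.DataFrame(rows).set_index("variable"))
    return written


def load_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a flat TOML file."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    valid = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    for key in ("alpha_bounds", "delta_bounds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


def tree_uncertainty_replicates(
    backbone: Phylogeny,
    placements,
    table: TraitTable,
    n_trees: int = 100,
    seed: int = 0,
    n_permutations: int = 999,
) -> pd.DataFrame:
    """Signal-verdict stability over randomly re-grafted trees.

    The reference tree is the grafting obtained with ``seed``; each of the
    ``n_trees`` replicates re-grafts with a fresh seed and repeats the K
    permutation test per variable.  Returns one row per variable with the
    fraction of replicate trees whose significance verdict (alpha = 0.05)
    matches the reference tree's.
    """
    rng = np.random.default_rng(seed)

    def verdicts(tree: Phylogeny) -> dict[str, bool]:
        tree, tab = prepare_inputs(tree, table)
        logx = tab.log10()
        out = {}
        for el in tab.elements:
            res = signal.k_permutation_test(
                tree, logx[el].to_dict(), n_perm=n_permutations, seed=int(rng.integers(2**63))
            )
            out[el] = res.p_value < 0.05
        return out

    ref_tree = graft_missing_taxa(backbone, placements, seed=int(rng.integers(2**63)))
    ref = verdicts(ref_tree)
    counts = {el: 0 for el in ref}
    for _ in range(n_trees):
        rep_tree = graft_missing_taxa(backbone, placements, seed=int(rng.integers(2**63)))
        rep = verdicts(rep_tree)
        for el in counts:
            counts[el] += int(rep[el] == ref[el])
    rows = [
        {
            "variable": el,
            "reference_significant": ref[el],
            "fraction_matching": counts[el] / n_trees,
        }
        for el in counts
    ]
    return pd.DataFrame(rows)
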