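"""Non-phylogenetic description of multi-element leaf composition.

Log10 transform, life-form group summaries with one-way ANOVA, principal
component analysis of the species-by-element matrix, and fold-range
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ELEMENTS",
    "LIFE_FORMS",
    "TraitTable",
    "PcaResult",
    "summarize_groups",
    "pca_scores",
    "fold_ranges",
]

ELEMENTS = ("C", "N", "P", "K", "Ca", "Mg")
LIFE_FORMS = ("fern", "herb", "evergreen", "deciduous")
HERBACEOUS = ("fern", "herb")
WOODY = ("evergreen", "deciduous")

GROUPINGS = {
    "herbaceous/woody": {
        "fern": "herbaceous", "herb": "herbaceous",
        "evergreen": "woody", "deciduous": "woody",
    },
    "evergreen/deciduous": {"evergreen": "evergreen", "deciduous": "deciduous"},
    "fern/herb": {"fern": "fern", "herb": "herb"},
}


@dataclass
class TraitTable:
    """Validated species x element concentration table with life-form labels.

    ``data`` is indexed by species and holds strictly positive concentrations
    (mg/g) in one column per element plus a ``life_form`` column.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate species labels: {dups}")
        if "life_form" not in df.columns:
            raise ValueError("trait table needs a 'life_form' column")
        bad = sorted(set(df["life_form"]) - set(LIFE_FORMS))
        if bad:
            raise ValueError(f"unknown life forms {bad}; expected {LIFE_FORMS}")
        if df["life_form"].isna().any():
            raise ValueError("missing life-form labels")
        if not self.elements:
            raise ValueError(f"no element columns found (expected some of {ELEMENTS})")
        vals = df[list(self.elements)]
        if vals.isna().any().any():
            raise ValueError("missing element concentrations")
        if (vals <= 0).any().any():
            raise ValueError("element concentrations must be strictly positive")

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        df = pd.read_csv(path)
        if "species" in df.columns:
            df = df.set_index("species")
        return cls(df)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e for e in ELEMENTS if e in self.data.columns)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def concentrations(self) -> pd.DataFrame:
        return self.data[list(self.elements)].astype(float)

    def log10(self) -> pd.DataFrame:
        """Log10-transformed concentrations (the scale of all phylogenetic fits)."""
        return np.log10(self.concentrations())

    def coarse_life_form(self) -> pd.Series:
        """herbaceous (fern + herb) vs woody (evergreen + deciduous)."""
        return self.data["life_form"].map(GROUPINGS["herbaceous/woody"])


@dataclass(frozen=True)
class PcaResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # species x components
    explained: np.ndarray  # proportion of variance per component

    @property
    def pc1_pc2_percent(self) -> float:
        return float(100.0 * self.explained[:2].sum())


def summarize_groups(
    table: TraitTable,
    grouping: str = "herbaceous/woody",
    extra_columns: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group mean +/- SE with one-way ANOVA per variable.

    Element concentrations are summarized on the raw scale but tested on
    log10 values; ``extra_columns`` (e.g. PC scores) are tested as given.
    Rows carry group letters (same letter = no significant difference at
    alpha 0.05; with two groups the letters follow the single F test).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {sorted(GROUPINGS)}")
    mapping = GROUPINGS[grouping]
    labels = table.data["life_form"].map(mapping).dropna()
    groups = sorted(set(mapping.values()), key=list(mapping.values()).index)
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    raw = table.concentrations().loc[labels.index]
    tested = table.log10().loc[labels.index]
    if extra_columns is not None:
        extra = extra_columns.loc[labels.index]
        raw = pd.concat([raw, extra], axis=1)
        tested = pd.concat([tested, extra], axis=1)

    rows = []
    for var in raw.columns:
        by_group = {g: tested.loc[labels == g, var].to_numpy() for g in groups}
        pooled = np.concatenate(list(by_group.values()))
        if np.ptp(pooled) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*by_group.values())
            if np.isnan(f_stat):  # zero within-group variance edge cases
                f_stat, p = 0.0, 1.0
        sig = p < 0.05
        for gi, g in enumerate(groups):
            vals = raw.loc[labels == g, var].to_numpy(dtype=float)
            letter = chr(ord("A") + gi) if sig else "A"
            rows.append(
                {
                    "variable": var,
                    "group": g,
                    "n": vals.size,
                    "mean": float(np.mean(vals)),
                    "se": float(np.std(vals, ddof=1) / np.sqrt(vals.size)),
                    "F": float(f_stat),
                    "p_value": float(p),
                    "letter": letter,
                }
            )
    return pd.DataFrame(rows)


def pca_scores(
    table: TraitTable, scale: str = "correlation", log10: bool = True
) -> PcaResult:
    """PCA of the species x element matrix.

    ``scale='correlation'`` standardizes columns to unit variance (default);
    ``'covariance'`` centers only.  Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    X = table.log10() if log10 else table.concentrations()
    if table.n < 3:
        raise ValueError("PCA requires at least 3 species")
    M = X.to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [c for c, s in zip(X.columns, sd) if s == 0]
        raise ValueError(f"constant columns: {const}")
    M = M - M.mean(axis=0)
    if scale == "correlation":
        M = M / sd
    elif scale != "covariance":
        raise ValueError("scale must be 'correlation' or 'covariance'")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    # deterministic signs
    for j in range(Vt.shape[0]):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2 / (M.shape[0] - 1)
    explained = var / var.sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comps)
    scores = pd.DataFrame(U * s, index=X.index, columns=comps)
    return PcaResult(loadings=loadings, scores=scores, explained=explained)


def fold_ranges(table: TraitTable) -> pd.Series:
    """Max/min concentration ratio per element across all species."""
    conc = table.concentrations()
    return conc.max() / conc.min()
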