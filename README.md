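# phyloniche

Phylogenetic comparative analysis of multi-element leaf composition
("biogeochemical niche" evolution): phylogenetic-signal testing, competing
trait-evolution model fits, optimum-shift detection, phylogenetic regression,
and multivariate niche descriptives — plus simulators with known ground truth
so every stage is verifiable without external data.

## What it does

Given a rooted ultrametric phylogeny (Newick) and a species trait table
(CSV: `species, C, N, P, K, Ca, Mg, life_form` with life forms
fern / herb / evergreen / deciduous), the package runs:

1. **Descriptives** — log10 transform, life-form group summaries with
   one-way ANOVA, correlation-matrix PCA, per-element fold ranges.
2. **Phylogenetic signal** — Blomberg's K per element and per PC score,
   with a 999-permutation randomization test.
3. **Model comparison** — ML fits of five trait-evolution models compared
   by AICc (ΔAICc < 2 = equivalence):
   - `BM` single-rate Brownian motion (closed form),
   - `BMM` two-rate BM (herbaceous vs woody regimes via Fitch painting),
   - `DELTA` Pagel's δ node-depth power transform (with a χ²₁ LRT vs δ = 1),
   - `OU1` single-optimum Ornstein–Uhlenbeck,
   - `OUM` two-optimum Hansen model.
4. **Optimum-shift detection** — greedy forward search for OU optimum
   shifts under a penalized criterion
   `-2 lnL + (3+m) ln n + 2m ln E` (per-shift size + placement cost).
5. **PGLS** — pairwise element regressions with simultaneously ML-estimated
   Pagel's λ (lower-triangular slope/significance matrix).
6. **Tree-uncertainty replication** — re-graft missing taxa onto a backbone
   many times and report the stability of signal verdicts.

All likelihoods reduce to GLS with profiled mean and scale over a structured
covariance, optimized by bounded 1-D search; every model is checked in the
test suite against brute-force multivariate-normal densities assembled by
independent lineage-segment enumeration.

## CLI

```sh
phyloniche simulate --study-fixture --seed 1 --out-prefix fixture
    # writes fixture.nwk, fixture.csv, fixture.truth.json (102-species
    # synthetic data mimicking the study's group structure)

phyloniche run fixture.nwk fixture.csv --out report.json   # full analysis
phyloniche signal fixture.nwk fixture.csv                  # Blomberg's K table
phyloniche fit fixture.nwk fixture.csv --element Ca        # 5-model comparison
phyloniche shifts fixture.nwk fixture.csv --element Ca     # optimum shifts
phyloniche pgls fixture.nwk fixture.csv                    # pairwise slopes
phyloniche describe fixture.csv                            # ANOVA + PCA
phyloniche tree-replicates backbone.nwk placements.csv traits.csv
    # placements.csv: columns new_tip, anchor_tips (semicolon-separated)
```

## Library example

```python
from phyloniche import (read_newick, rescale_depth, TraitTable,
                        k_permutation_test, fit_oum, paint_regimes)

tree = rescale_depth(read_newick(open("tree.nwk").read()))
table = TraitTable.from_csv("traits.csv")
trait = table.log10()["Ca"].to_dict()
res = k_permutation_test(tree, trait, n_perm=999, seed=1)
painting = paint_regimes(tree, table.coarse_life_form().to_dict())
fit = fit_oum(tree, trait, painting)
```

## Layout

- `src/phyloniche/phylo_core.py` — trees, covariance, regime painting, grafting
- `src/phyloniche/signal.py` — Blomberg's K + permutation test
- `src/phyloniche/evo_models.py` — BM / BMM / δ / OU1 / OUM, AICc comparison
- `src/phyloniche/shifts.py` — penalized optimum-shift search
- `src/phyloniche/pgls.py` — λ-PGLS and the pairwise element matrix
- `src/phyloniche/niche_descriptives.py` — ANOVA, PCA, fold ranges
- `src/phyloniche/synthetic_data.py` — Yule trees, regime and trait simulators
- `src/phyloniche/pipeline.py`, `cli.py` — orchestration and CLI
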