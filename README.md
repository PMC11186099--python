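# acnmf

Automatic consensus non-negative matrix factorization for single-cell
RNA-seq: discover gene expression programs that are *reproducible*, and
let the data — not the rank — decide how many there are.

## The problem

NMF factorizes a genes × cells count matrix **Y ≈ W·H** into gene
expression programs (columns of **W**) and per-cell activities (rows of
**H**). Choosing the rank *k* is notoriously arbitrary, and different
choices give different descriptions of the same tissue. `acnmf`
implements a split-half reproducibility criterion: cells are split 50/50,
each half is consensus-factorized independently, and programs count only
if a Bonferroni-significant top-*J*-gene overlap (exact hypergeometric
test) links a program in one half to a program in the other. Plotting the
number of replicated program communities against *k* produces a curve
that plateaus at the true number of programs for *every* *k* above it —
so program recovery is decoupled from rank selection. The inflection of
the loess-smoothed curve selects *k\**, and the Jaccard length *J\** is
the one whose post-inflection cost decays with slope closest to −1
(a flat plateau on normalized axes).

The package also builds significance-tested graphs linking programs
across datasets (walktrap communities, Fruchterman–Reingold layout,
GraphML/JSON export), annotates programs by one-sided Wilcoxon rank-sum
marker-set enrichment, and classifies ambiguous cells as cancer or normal
from binned copy-number-like expression features with a Fisher-exact
comparison against the endothelial misclassification rate.

It ships a splatter-style simulator (cell-type groups plus a shared
activity program, optional CNV overlay) so everything is testable without
any download.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from acnmf import SimConfig, simulate_counts, scan, select_jaccard_length, finalize_programs

ds = simulate_counts(SimConfig(n_cells=900, n_genes=1500, n_groups=5,
                               act_n_genes=100, lib_loc=8.0, seed=7))
curves = scan(ds.counts, k_grid=(3, 5, 7, 9, 11, 13), J_grid=(10, 20),
              n_reps=2, seed=1, n_hvg=600, n_restarts=10, max_iter=60)
for c in curves:
    print(f"J={c.jaccard_length} smoothed={[round(float(v),1) for v in c.smoothed]} "
          f"k*={c.k_star} slope={c.post_inflection_slope:.2f}")
J = select_jaccard_length(curves)
res = finalize_programs(ds.counts, 9, J, seed=2, n_hvg=600, n_restarts=10)
print(f"J*={J}, final programs: {res.final_programs.n_programs}")
```

prints

```
J=10 smoothed=[1.6, 4.7, 6.0, 7.0, 6.7, 5.9] k*=9 slope=-1.86
J=20 smoothed=[1.0, 4.4, 6.0, 6.5, 7.2, 7.1] k*=7 slope=-0.76
J*=20, final programs: 6
```

Five planted cell types plus one shared activity program: the
replicated-community count rises to ~6 by k = 7 and stays near 6 for
every larger rank. At J = 20 the post-inflection cost decays with slope
−0.76, closest to the ideal −1 of a perfectly flat plateau, so J\* = 20
is selected — and the finalized decomposition returns exactly the 6 real
programs even though the factorization rank was 9. Each program carries community-averaged
gene weights, Z-scored weights, and non-negative activities refit for all
cells.

The `examples/` directory has one short script per capability:
simulation, rank selection, the cross-dataset graph, marker enrichment,
and the CNV-based cancer/normal classifier.

## The benchmark script

`scripts/acceptance.py` recomputes the package's benchmark claims from
scratch: it simulates the default benchmark (13 cell types + 1 activity
program, 3,000 cells × 5,000 genes), runs the full scan over
k ∈ {6,…,30} and J ∈ {10, 20, 50} with 3 split replicates and 30 NMF
restarts, selects the Jaccard length by the slope rule, finalizes
programs at k = 22 and k = 14, and counts how many ground-truth programs
are recovered by the Bonferroni-corrected overlap test:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Takes roughly 10–15 minutes on one CPU. See `docs/methods.md` for the
model, its assumptions, parameter defaults, and known limitations.
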