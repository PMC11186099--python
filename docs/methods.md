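# Methods

## The problem

Non-negative matrix factorization (NMF) decomposes a genes × cells
single-cell RNA-seq count matrix Y into a basis of gene expression
programs W (genes × k) and per-cell program activities H (k × cells).
Programs can be discrete cell identities or shared biological activities
(cell cycle, stress, treatment response). The persistent difficulty is
choosing the rank k: there is no ground truth, and different k give
different — often equally plausible — representations of the same tissue.

The approach implemented here decouples *recovering programs* from
*choosing k*. Cells are split 50/50 at random and each half is factorized
independently; a program is treated as real only if a statistically
matching program appears in both halves. The number of such replicated
programs, not k itself, is the quantity of interest: on data with a known
number of programs it plateaus at the true count for every k above it.

## The procedure

1. **Preparation.** Counts are optionally subsampled to 50,000 cells.
   2,000 highly variable genes are selected once on the full matrix by a
   Fano-factor dispersion score (variance/mean on depth-normalized
   counts), so both halves share one gene universe. Each gene row is
   scaled to unit variance without centering (non-negativity preserved).
   Whether the original workflow scaled or used raw HVG counts is not
   documented; scaling is the default here and raw counts are one flag
   away.

2. **Consensus factorization per half.** At each rank k, NMF is run from
   many random restarts (200 at full scale, 30 in the desk-scale
   configuration). The pooled basis columns are L2-normalized; the most
   isolated 10% (mean Euclidean distance to the ~0.3 × n_restarts nearest
   other columns) are discarded; k-means clusters the survivors into k
   groups, whose element-wise medians (re-normalized) are the consensus
   programs. Components are put in a canonical order before clustering so
   the result does not depend on pooling order. Gene weights are Z-scored
   per program for set-overlap testing.

   Two solvers are available: monotone multiplicative updates (the
   reference; records its objective trajectory) and scikit-learn's
   HALS/coordinate descent, which is several-fold faster and is the
   default in scans. Both minimize the Frobenius loss from seeded random
   initializations.

3. **Split matching.** For each program, the top-J Z-scored genes form a
   set (J is the "Jaccard length"). Every cross-split pair of programs is
   tested: under the null that two fixed-size sets are independent draws
   from the G-gene universe, the intersection is hypergeometric, and the
   upper tail gives an exact p-value. This replaces the asymptotic
   jaccard.test approximation used in the original workflow — for fixed
   set sizes the two order pairs identically under the null, and the
   exact tail needs no external package. Pairs significant after
   Bonferroni correction over all k_a × k_b comparisons (α = 0.05) become
   edges of a bipartite graph.

4. **Community counting.** Girvan–Newman edge-betweenness clustering,
   with the dendrogram cut at maximum modularity, counts the replicated
   program communities. Nodes with no significant partner never enter the
   graph.

5. **Rank and Jaccard-length selection.** Steps 1–4 are repeated for a
   grid of k, a grid of J, and several independent split replicates
   (3 at desk scale, 200 at full scale). Per J, a loess curve (tricube
   weights, local quadratic, span 0.75) is fit through the
   (k, community-count) scatter. Both axes are min-max normalized so the
   chord from the first to the last point is the identity line; the
   vertical residual above the chord peaks at the inflection k*, and the
   residuals beyond k* ("cost values") are regressed on k. On these
   normalized axes a perfectly flat plateau — the replicated count no
   longer growing with k — gives a cost slope of exactly −1, which is why
   the J whose slope is closest to −1 is selected. (On raw axes the
   slope magnitude depends on the units of k and the community count and
   the −1 criterion loses its meaning; normalization is therefore the
   default here.)

6. **Final programs.** At the chosen (k*, J*), one fresh seeded split is
   consensus-factorized; each community's final gene weights are the mean
   of its member consensus loadings (raw scale, then re-Z-scored), and
   activities for *all* cells are refit by non-negative least squares
   against the averaged basis (solved through the Cholesky factor of WᵀW,
   so the per-cell problems are k × k). Averaging on raw loadings rather
   than Z-scores is a choice; a flag switches it.

## Cross-dataset comparison

Program catalogs from different datasets are compared pairwise with the
same exact overlap test, each dataset contributing its own tuned J (the
"asymmetric" test — interpreted as differing per-dataset set sizes, not a
directional index). The universe is the intersection of the catalogs'
gene lists. Edges are kept at Bonferroni FWER < 0.05 by default (0.01 is
one argument away; the original description uses both thresholds in
different places). Communities come from walktrap random walks cut at
maximum modularity; the layout is seeded Fruchterman–Reingold; exports
are GraphML or JSON node-link, lossless for attributes and layout.

## Annotation and the CNV classifier

A program is annotated by a one-sided Wilcoxon rank-sum test of a marker
set's weights against all other gene weights (exact null when the smaller
group has ≤ 20 members and there are no ties, tie-corrected normal
approximation otherwise). Markers absent from the universe are dropped
and counted, not treated as bottom ranks. Cells "highly expressing" a
program are selected by a strict activity threshold: h > 50 for
annotation displays and h > 100 for classifier labeling, by the source
convention. Signature summaries use log1p depth-normalized expression
(the exact normalization behind the original displays is unstated).

The cancer/normal classifier uses "manual" copy-number features: per
gene, log1p TPM-like expression standardized by reference (immune) cell
mean/SD and clipped to ±3 (limits single-gene dropout artifacts, a choice
not documented upstream); per bin of 50 genomically consecutive genes
(trailing bins ≥ 25 genes kept, smaller merged), the mean over member
genes. Models (regularized logistic regression, random forest, or a
linear-margin SVM with a sigmoid-squashed margin for probabilities) are
trained on 75% of clear cancer cells plus immune cells, scored on the
held-out 25% (balanced accuracy), and applied to never-trained-on
endothelial cells (misclassification-rate reference) and ambiguous
mesenchymal-like cells. Fisher's exact test (two-sided,
minimum-likelihood convention; conditional-MLE odds ratio) compares the
two cancer-call rates. An external inferred-CNV feature matrix can be
plugged in wherever the manual features are accepted; no CNV HMM is
re-implemented here.

## The simulator

`acnmf.simulate` follows the splatter generative family: per-gene base
mean ~ Gamma(0.6, rate 0.3); per-group DE factors log-normal, reflected
to ≥ 1 and inverted with probability 0.5, on 10% of genes per group;
library size ~ LogNormal(9, 0.2) (~8,000 UMIs/cell, a typical 10x depth
for a 5,000-gene panel); counts ~ Poisson(Gamma) with splatter's
mean-dependent BCV trend (bcv_common 0.1, df 60). One activity program
(300 genes, log-normal factors ≥ 1, location 0.7 ≈ two-fold) is overlaid
multiplicatively on 20% of cells drawn uniformly across groups. The DE
factor location is 0.5 rather than splatter's 0.1: the benchmark's groups
represent distinct cell types, which differ by several-fold expression of
many genes, whereas splatter's default describes subtle within-type
perturbations. The default benchmark is 13 groups + 1 activity program.

Three suggested noise conditions are exposed through `bcv_common`
(0.1 / 0.25 / 0.4 as low/medium/high); the original simulation's three
signal:noise levels are not numerically documented, so no fidelity to
them is claimed.

What the simulator does *not* emulate: ambient RNA, doublets, batch
effects, gene-gene correlation beyond programs, zero inflation beyond
Gamma-Poisson, or realistic gene-length/GC structure. A green benchmark
therefore establishes that the procedure recovers multiplicative planted
programs at realistic depth and overdispersion — not robustness to the
full messiness of real tissue. The CNV overlay re-draws counts of
affected cells with segment rates rescaled (not post-multiplied), on 20
synthetic pseudo-chromosomes; its cell "roles" (cancer/ambiguous/normal)
are generator bookkeeping for classifier evaluation.

## Scales, defaults, and runtime

Two presets:

* `scaled` (desk): 3,000 cells × 5,000 genes, k ∈ {6,…,30 step 4},
  J ∈ {10, 20, 50}, 30 restarts, 3 split replicates, HALS with ≤ 60–100
  iterations. The full benchmark (simulate → scan → select → finalize at
  two ranks → truth matching) runs in ~10–15 min on one CPU.
* `full`: 15,000+ cells, k ∈ {2,…,200}, J ∈ {10,…,200}, 200 restarts,
  200 replicates — the published-workflow scale. This (and the real
  patient/model cohorts, which sit behind controlled-access accessions)
  is documented and configurable but is hours of compute; it is not part
  of the desk-scale test surface.

Numerical choices worth knowing: NMF restarts use float32 in scans
(halves runtime; community counts are unchanged in practice); k-means
uses 10 seeded initializations; ties in gene rankings break
lexicographically by gene id; the elbow is the leftmost maximal residual;
a curve that never bends is flagged degenerate rather than silently
yielding a rank; Bonferroni families are k_a × k_b per split comparison
and all cross-dataset pairs for the graph.

## Known limitations

* Girvan–Newman cut at maximum modularity maximizes modularity only over
  its own dendrogram. On small graphs with weak community structure
  (best modularity ≲ 0.2) it can report fewer communities than exhaustive
  max-modularity partitioning; igraph's edge-betweenness clustering
  behaves identically. On the near-bipartite-matching graphs this package
  builds, structure is strong and the distinction has not been observed
  to matter.
* At desk scale the under-factorization behavior at k = truth (merging or
  splitting that loses one program) is seed-dependent: some splits
  recover all 14 planted programs even at k = 14.
* The hypergeometric overlap test conditions on fixed set sizes; it is
  exact for the top-J construction used here but not for sets of
  data-dependent size.
* Activity refit by NNLS assumes the averaged basis spans the cells'
  expression; rank-deficient bases trigger a warning and a small ridge.
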