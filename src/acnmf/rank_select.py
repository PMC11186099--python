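"""Automatic rank and Jaccard-length selection by split-half reproducibility.

The central idea: factorize two random halves of the cells independently;
a program is "real" if a significantly overlapping program (by top-J gene
sets) appears in both halves. Program pairs whose overlap passes a
Bonferroni-corrected hypergeometric test become edges of a bipartite
graph; Girvan-Newman community detection (cut at maximum modularity)
counts the replicated program communities. Repeating this over a grid of
ranks k and Jaccard lengths J yields community-count curves; loess
smoothing plus chord-residual elbow detection locates the rank k* at the
inflection, and the Jaccard length whose post-inflection cost decays with
slope closest to -1 (on min-max-normalized axes, where -1 means "the
replicated count stays constant above the true rank") is selected.

The number of communities plateaus at the number of true programs for all
k above it, decoupling program recovery from exact rank choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .consensus import consensus_factorize, refit_activities, zscore_weights
from .preprocess import CountMatrix, scale_for_nmf, select_hvg, split_half

__all__ = [
    "JaccardTestResult",
    "CommunityCurve",
    "ProgramSet",
    "AcnmfResult",
    "top_genes",
    "jaccard_test",
    "match_split_programs",
    "count_communities",
    "scan",
    "loess_smooth",
    "find_inflection",
    "select_jaccard_length",
    "finalize_programs",
    "match_to_truth",
]


@dataclass
class JaccardTestResult:
    set_size_a: int
    set_size_b: int
    universe_size: int
    intersection: int
    jaccard_index: float
    p_raw: float
    p_adjusted: float


@dataclass
class CommunityCurve:
    """Replicated-community counts over the k grid for one Jaccard length."""

    jaccard_length: int
    points: list  # (k, replicate_id, n_communities)
    k_grid: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    k_star: int | None = None
    cost_points: list | None = None  # (k, residual) for k > k_star, normalized axes
    post_inflection_slope: float | None = None
    degenerate: bool = False

    def fit(self, span: float = 0.75) -> "CommunityCurve":
        """Smooth the scatter, locate the inflection, and record the cost slope."""
        ks = np.array([p[0] for p in self.points], dtype=float)
        ys = np.array([p[2] for p in self.points], dtype=float)
        grid = np.unique(ks)
        sm = loess_smooth(list(zip(ks, ys)), span=span, grid=grid)
        k_star, residuals, degenerate = find_inflection(list(zip(grid, sm)))
        self.k_grid, self.smoothed = grid, sm
        self.k_star, self.degenerate = int(k_star), degenerate
        self.cost_points = [(k, r) for k, r in residuals if k > k_star]
        if len(self.cost_points) >= 2:
            # OLS of cost vs k on min-max normalized axes: a flat plateau
            # above the inflection gives slope exactly -1
            kr = grid.max() - grid.min()
            xs = np.array([(k - grid.min()) / kr for k, _ in self.cost_points])
            cs = np.array([r for _, r in self.cost_points])
            self.post_inflection_slope = float(np.polyfit(xs, cs, 1)[0])
        return self


@dataclass
class ProgramSet:
    """Final community-averaged programs with refit activities."""

    program_ids: list
    gene_ids: np.ndarray
    gene_weights: np.ndarray  # genes x n_programs, community means (raw scale)
    wz: np.ndarray  # re-Z-scored weights
    activities: np.ndarray | None  # n_programs x cells
    member_nodes: list  # list of node lists per program

    @property
    def n_programs(self) -> int:
        return self.gene_weights.shape[1]


@dataclass
class AcnmfResult:
    chosen_k: int
    chosen_J: int
    program_graph: nx.Graph
    communities: list
    final_programs: ProgramSet


def top_genes(wz_column: np.ndarray, J: int, gene_ids) -> np.ndarray:
    """The J genes with largest Z-scored weight; ties broken by gene id."""
    if J <= 0:
        raise ValueError("J must be positive")
    gene_ids = np.asarray(gene_ids, dtype=object)
    if J > len(gene_ids):
        raise ValueError("J exceeds the gene universe")
    order = sorted(range(len(gene_ids)), key=lambda i: (-wz_column[i], gene_ids[i]))
    return gene_ids[np.array(order[:J])]


def jaccard_test(A, B, universe_size: int) -> JaccardTestResult:
    """Jaccard index of two gene sets with an exact hypergeometric overlap test.

    Under the null that A and B are independent uniform draws of their
    fixed sizes from a universe of ``universe_size`` genes, the
    intersection is Hypergeometric; ``p_raw`` is the upper tail
    P(X >= |A & B|).
    """
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("sets must be non-empty")
    if universe_size < len(A | B):
        raise ValueError("universe smaller than the union of the sets")
    inter = len(A & B)
    union = len(A | B)
    p = float(hypergeom.sf(inter - 1, universe_size, len(A), len(B)))
    return JaccardTestResult(
        set_size_a=len(A),
        set_size_b=len(B),
        universe_size=universe_size,
        intersection=inter,
        jaccard_index=inter / union,
        p_raw=p,
        p_adjusted=p,
    )


def match_split_programs(
    Wz_a: np.ndarray,
    Wz_b: np.ndarray,
    gene_ids,
    J: int,
    alpha: float = 0.05,
) -> list[tuple[int, int, JaccardTestResult]]:
    """Test all cross-split program pairs; Bonferroni over k_a x k_b tests.

    Returns edges ``(i, j, result)`` for split-A program i vs split-B
    program j with adjusted p < alpha. Both factorizations must share the
    same gene universe (``gene_ids``, the rows of both Wz matrices).
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    if Wz_a.shape[0] != len(gene_ids) or Wz_b.shape[0] != len(gene_ids):
        raise ValueError("weight matrices do not share the gene universe")
    G = len(gene_ids)
    ka, kb = Wz_a.shape[1], Wz_b.shape[1]
    n_tests = ka * kb
    sets_a = [frozenset(top_genes(Wz_a[:, i], J, gene_ids)) for i in range(ka)]
    sets_b = [frozenset(top_genes(Wz_b[:, j], J, gene_ids)) for j in range(kb)]
    edges = []
    for i in range(ka):
        for j in range(kb):
            res = jaccard_test(sets_a[i], sets_b[j], G)
            res.p_adjusted = min(1.0, res.p_raw * n_tests)
            if res.p_adjusted < alpha:
                edges.append((i, j, res))
    return edges


def count_communities(edges) -> tuple[int, list]:
    """Count communities by Girvan-Newman edge betweenness, cut at max modularity.

    ``edges`` is an iterable of node pairs (any hashables) or
    ``(u, v, attr)`` triples. Nodes with no edges never enter the graph.
    Returns ``(n_communities, partition)``.
    """
    g = nx.Graph()
    for e in edges:
        g.add_edge(e[0], e[1])
    if g.number_of_edges() == 0:
        return 0, []
    best = [set(c) for c in nx.connected_components(g)]
    best_q = nx.community.modularity(g, best)
    for partition in nx.community.girvan_newman(g):
        part = [set(c) for c in partition]
        q = nx.community.modularity(g, part)
        if q > best_q + 1e-12:
            best, best_q = part, q
    return len(best), best


def loess_smooth(points, span: float = 0.75, grid=None) -> np.ndarray:
    """Locally weighted quadratic regression (tricube weights).

    ``points`` is a sequence of (x, y). The fit is evaluated at ``grid``
    (default: the sorted unique x values). Deterministic; exactly
    reproduces polynomials up to degree 2 when the window covers them.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct x values")
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    n = len(x)
    window = max(4, int(np.ceil(span * n)))
    fitted = np.empty(len(grid))
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        cutoff = np.sort(d)[min(window, n) - 1]
        if cutoff == 0:
            cutoff = max(d.max(), 1.0)
        w = np.clip(1.0 - (d / (cutoff * (1 + 1e-12))) ** 3, 0.0, None) ** 3
        use = w > 0
        deg = 2 if use.sum() > 3 else 1
        X = np.vander(x[use] - x0, deg + 1)
        WX = X * w[use, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y[use], rcond=None)
        fitted[gi] = beta[-1]
    return fitted


def find_inflection(smoothed) -> tuple[float, list, bool]:
    """Elbow of a concave curve by the chord-residual rule.

    Axes are min-max normalized so the chord from the first to the last
    point is the identity line; the residual r(k) = y_norm(k) - x_norm(k)
    peaks at the inflection. Returns ``(k_star, [(k, residual), ...],
    degenerate_flag)``; the flag is set when the curve is essentially
    linear (max residual ~ 0). Ties go to the leftmost k.
    """
    pts = np.asarray(smoothed, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    k, y = pts[:, 0], pts[:, 1]
    order = np.argsort(k)
    k, y = k[order], y[order]
    kr = k[-1] - k[0]
    yr = y[-1] - y[0]
    xn = (k - k[0]) / kr
    yn = (y - y[0]) / yr if abs(yr) > 1e-12 else np.zeros_like(y)
    resid = yn - xn
    k_star = k[int(np.argmax(resid))]
    degenerate = bool(resid.max() < 1e-9)
    return float(k_star), list(zip(k, resid)), degenerate


def select_jaccard_length(curves: list[CommunityCurve]) -> int:
    """Pick the Jaccard length whose post-inflection cost slope is closest to -1.

    On normalized axes a slope of exactly -1 means the replicated-program
    count is constant for every k above the inflection — the behavior of a
    correctly resolved program set. Ties go to the smaller J.
    """
    candidates = []
    for c in curves:
        if c.post_inflection_slope is None:
            continue
        candidates.append((abs(c.post_inflection_slope - (-1.0)), c.jaccard_length))
    if not candidates:
        raise ValueError("no curve has enough post-inflection points")
    if len(candidates) == 1:
        warnings.warn("single candidate Jaccard length; returned without competition")
    candidates.sort()
    return candidates[0][1]


def scan(
    counts: CountMatrix,
    k_grid,
    J_grid,
    n_reps: int = 3,
    seed: int = 0,
    n_hvg: int = 2000,
    n_restarts: int = 30,
    alpha: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-4,
    solver: str = "hals",
    dtype=np.float32,
) -> list[CommunityCurve]:
    """Replicated split-half scans over the (k, J) grid.

    Each replicate draws a fresh 50/50 cell split, runs consensus NMF on
    both halves at every k, and counts replicated program communities at
    every Jaccard length. Highly variable genes are selected once on the
    full matrix so both halves share a gene universe. Everything is seeded.
    """
    k_grid = sorted(int(k) for k in k_grid)
    J_grid = sorted(int(J) for J in J_grid)
    if not k_grid or not J_grid:
        raise ValueError("empty grid")
    hvg = select_hvg(counts, n_hvg=n_hvg)
    if max(J_grid) > len(hvg):
        raise ValueError("Jaccard length exceeds the gene universe")
    curves = {J: CommunityCurve(jaccard_length=J, points=[]) for J in J_grid}
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_reps) % (2**31)
    for rep, rs in enumerate(rep_seeds):
        pair = split_half(counts, seed=int(rs))
        halves = []
        for idx in (pair.indices_a, pair.indices_b):
            X, genes = scale_for_nmf(counts.subset_cells(idx), hvg)
            halves.append((X.astype(dtype), genes))
        if not np.array_equal(halves[0][1], halves[1][1]):
            shared = np.array(
                [g for g in halves[0][1] if g in set(halves[1][1])], dtype=object
            )
            halves = [
                (X[np.isin(genes, shared)], shared) for X, genes in halves
            ]
        genes = halves[0][1]
        for ki, k in enumerate(k_grid):
            cons = [
                consensus_factorize(
                    X, k, n_restarts=n_restarts, seed=int(rs) + 1000 * ki + s_off,
                    max_iter=max_iter, tol=tol, solver=solver, refit=False,
                )
                for s_off, (X, _) in zip((1, 2), halves)
            ]
            for J in J_grid:
                edges = match_split_programs(cons[0].Wz, cons[1].Wz, genes, J, alpha)
                n_comm, _ = count_communities((f"a{i}", f"b{j}") for i, j, _ in edges)
                curves[J].points.append((k, rep, n_comm))
    return [curves[J].fit() for J in J_grid]


def finalize_programs(
    counts: CountMatrix,
    chosen_k: int,
    chosen_J: int,
    seed: int = 0,
    n_hvg: int = 2000,
    n_restarts: int = 30,
    alpha: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-4,
    solver: str = "hals",
    dtype=np.float32,
) -> AcnmfResult:
    """Consensus programs at the chosen (k, J): average over each community.

    A fresh seeded 50/50 split is consensus-factorized at ``chosen_k``;
    the replicated-program graph at ``chosen_J`` is cut into communities;
    each community's final gene weights are the mean of its member
    consensus loadings (raw scale), re-Z-scored; activities are refit for
    all cells against the averaged weights by non-negative least squares.
    """
    hvg = select_hvg(counts, n_hvg=n_hvg)
    pair = split_half(counts, seed=seed)
    halves = []
    for idx in (pair.indices_a, pair.indices_b):
        X, genes = scale_for_nmf(counts.subset_cells(idx), hvg)
        halves.append((X.astype(dtype), genes))
    if not np.array_equal(halves[0][1], halves[1][1]):
        shared = np.array(
            [g for g in halves[0][1] if g in set(halves[1][1])], dtype=object
        )
        halves = [(X[np.isin(genes, shared)], shared) for X, genes in halves]
    genes = halves[0][1]
    cons = [
        consensus_factorize(
            X, chosen_k, n_restarts=n_restarts, seed=seed + off,
            max_iter=max_iter, tol=tol, solver=solver, refit=False,
        )
        for off, (X, _) in zip((1, 2), halves)
    ]
    edges = match_split_programs(cons[0].Wz, cons[1].Wz, genes, chosen_J, alpha)
    graph = nx.Graph()
    for i, j, res in edges:
        graph.add_edge(("a", i), ("b", j), jaccard=res.jaccard_index, p=res.p_adjusted)
    n_comm, partition = count_communities(
        ((("a", i), ("b", j)) for i, j, _ in edges)
    )
    if n_comm == 0:
        raise RuntimeError(
            f"no replicated program communities at k={chosen_k}, J={chosen_J}"
        )
    W_by_split = {"a": cons[0].W_consensus, "b": cons[1].W_consensus}
    weights, members = [], []
    for comm in sorted(partition, key=lambda c: sorted(c)[0]):
        nodes = sorted(comm)
        weights.append(
            np.mean([W_by_split[s][:, p] for s, p in nodes], axis=0)
        )
        members.append(nodes)
    W_final = np.column_stack(weights)
    X_all, genes_all = scale_for_nmf(counts, genes)
    H_final = refit_activities(X_all, W_final)
    programs = ProgramSet(
        program_ids=[f"program_{i + 1}" for i in range(n_comm)],
        gene_ids=genes,
        gene_weights=W_final,
        wz=zscore_weights(W_final),
        activities=H_final,
        member_nodes=members,
    )
    return AcnmfResult(
        chosen_k=chosen_k,
        chosen_J=chosen_J,
        program_graph=graph,
        communities=[sorted(c) for c in partition],
        final_programs=programs,
    )


def match_to_truth(
    programs: ProgramSet, truth_sets, J: int, alpha: float = 0.05
) -> int:
    """Count ground-truth gene sets recovered by at least one program.

    Each program's top-J genes are tested against every truth set by the
    hypergeometric overlap test, Bonferroni-corrected over all
    program x truth comparisons; a truth set counts as recovered if any
    program matches it at adjusted p < alpha.
    """
    gene_ids = programs.gene_ids
    universe = set(gene_ids)
    G = len(universe)
    prog_sets = [
        frozenset(top_genes(programs.wz[:, i], J, gene_ids))
        for i in range(programs.n_programs)
    ]
    truth_in_universe = [
        frozenset(g for g in ts if g in universe) for ts in truth_sets
    ]
    n_tests = len(prog_sets) * len(truth_in_universe)
    recovered = 0
    for ts in truth_in_universe:
        if not ts:
            continue
        for ps in prog_sets:
            p = jaccard_test(ps, ts, G).p_raw * n_tests
            if p < alpha:
                recovered += 1
                break
    return recovered
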