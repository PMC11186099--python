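"""Splatter-style simulation of single-cell counts with planted programs.

Generates a genes x cells UMI count matrix containing a configurable
number of discrete cell-type groups plus one shared "activity" program
overlaid across groups — the benchmark layout used to validate consensus
NMF rank selection. The generative model follows the splatter family:

* per-gene base mean ~ Gamma(mean_shape, 1/mean_rate)
* per-group differential-expression factors: with probability ``de_prob``
  a gene gets a log-normal fold factor (reflected to be >= 1, inverted
  with probability ``de_down_prob``)
* the activity program multiplies a random subset of genes by log-normal
  factors >= 1 in a random subset of cells drawn uniformly across groups
* per-cell library size ~ LogNormal(lib_loc, lib_scale)
* counts ~ Poisson(Gamma) with a mean-dependent biological coefficient of
  variation (``bcv_common``, ``bcv_df``) as in splatter's default path.

An optional copy-number overlay rescales contiguous genomic segments in
designated "cancer" cells, providing ground truth for the CNV-based
cancer/normal classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import CountMatrix

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "CNVOverlayConfig",
    "simulate_counts",
    "truth_gene_sets",
    "make_gene_coords",
    "cnv_overlay",
]


@dataclass
class SimConfig:
    """Parameters of the benchmark simulation.

    Defaults describe the scaled desk benchmark: 3,000 cells, 5,000 genes,
    13 equiprobable cell types plus one activity program carried by 20% of
    cells. Gamma/log-normal parameters follow splatter's defaults except
    the DE factor location, which is raised to 0.5 so that groups separate
    the way distinct cell types do in real tumors (splatter's default 0.1
    describes subtle within-type perturbations). ``n_cells=15_000`` with
    ``n_genes=10_000`` reproduces the full-scale benchmark layout.
    """

    n_cells: int = 3000
    n_genes: int = 5000
    n_groups: int = 13
    group_probs: np.ndarray | None = None
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 9.0
    lib_scale: float = 0.2
    de_prob: float = 0.1
    de_loc: float = 0.5
    de_scale: float = 0.4
    de_down_prob: float = 0.5
    act_cell_frac: float = 0.2
    act_n_genes: int = 300
    act_loc: float = 0.7
    act_scale: float = 0.3
    bcv_common: float = 0.1
    bcv_df: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("non-positive dimensions")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.act_n_genes > self.n_genes:
            raise ValueError("act_n_genes exceeds n_genes")
        if self.group_probs is None:
            self.group_probs = np.full(self.n_groups, 1.0 / self.n_groups)
        self.group_probs = np.asarray(self.group_probs, dtype=float)
        if len(self.group_probs) != self.n_groups:
            raise ValueError("group_probs length != n_groups")
        if abs(self.group_probs.sum() - 1.0) > 1e-12:
            raise ValueError("group_probs must sum to 1")
        for name in ("de_prob", "de_down_prob", "act_cell_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedDataset:
    """Counts plus the ground truth that produced them.

    ``truth_factors`` is genes x (n_groups + 1): one multiplicative factor
    vector per cell-type program and, in the last column, the activity
    program. ``activity_flag`` marks the cells carrying the activity
    program; ``role`` is filled by :func:`cnv_overlay`.
    """

    counts: CountMatrix
    group_label: np.ndarray
    activity_flag: np.ndarray
    truth_factors: np.ndarray
    program_names: list[str]
    config: SimConfig
    role: np.ndarray | None = None
    cnv_segments: pd.DataFrame | None = None

    @property
    def n_programs(self) -> int:
        return self.truth_factors.shape[1]


@dataclass
class CNVOverlayConfig:
    """Copy-number overlay: contiguous genomic segments gained/lost in cancer cells."""

    n_segments: int = 6
    segment_gene_span: int = 150
    gain_factor: float = 2.0
    loss_factor: float = 0.5
    cancer_cell_frac: float = 0.4
    ambiguous_cell_frac: float = 0.1
    ambiguous_mode: str = "as_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gain_factor > 1.0 > self.loss_factor > 0.0):
            raise ValueError("need gain_factor > 1 > loss_factor > 0")
        if self.ambiguous_mode not in ("as_normal", "as_cancer"):
            raise ValueError("ambiguous_mode must be 'as_normal' or 'as_cancer'")


def _lognormal_factors(rng, n, loc, scale, down_prob):
    """Log-normal fold factors reflected to >= 1, inverted with prob ``down_prob``."""
    f = rng.lognormal(loc, scale, size=n)
    f = np.where(f < 1.0, 1.0 / f, f)
    down = rng.random(n) < down_prob
    return np.where(down, 1.0 / f, f)


def _sample_counts(rng, lam, bcv_common, bcv_df):
    """Gamma-Poisson draw with splatter's mean-dependent BCV trend."""
    n_genes = lam.shape[0]
    chisq = rng.chisquare(bcv_df, size=n_genes)
    with np.errstate(divide="ignore"):
        bcv = (bcv_common + 1.0 / np.sqrt(np.maximum(lam, 1e-12)))
    bcv = bcv * np.sqrt(bcv_df / chisq)[:, None]
    shape = 1.0 / bcv**2
    trended = rng.gamma(shape, lam / shape)
    return rng.poisson(trended).astype(np.int32)


def simulate_counts(cfg: SimConfig) -> SimulatedDataset:
    """Draw a full benchmark dataset from ``cfg`` (bit-reproducible per seed)."""
    rng = np.random.default_rng(cfg.seed)
    G, N, K = cfg.n_genes, cfg.n_cells, cfg.n_groups

    base_mean = rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=G)

    # per-group DE factors
    group_factors = np.ones((G, K))
    for g in range(K):
        de_mask = rng.random(G) < cfg.de_prob
        group_factors[de_mask, g] = _lognormal_factors(
            rng, int(de_mask.sum()), cfg.de_loc, cfg.de_scale, cfg.de_down_prob
        )

    # shared activity program: factors >= 1 on a random gene subset
    act_factors = np.ones(G)
    act_genes = rng.choice(G, size=cfg.act_n_genes, replace=False)
    act_factors[act_genes] = _lognormal_factors(
        rng, cfg.act_n_genes, cfg.act_loc, cfg.act_scale, down_prob=0.0
    )

    group = rng.choice(K, size=N, p=cfg.group_probs)
    n_act = int(round(cfg.act_cell_frac * N))
    act_cells = rng.choice(N, size=n_act, replace=False)
    act_flag = np.zeros(N, dtype=bool)
    act_flag[act_cells] = True

    libsize = rng.lognormal(cfg.lib_loc, cfg.lib_scale, size=N)

    # 2K unique expression profiles: (group, activity on/off)
    profiles = np.empty((G, 2 * K))
    for g in range(K):
        m = base_mean * group_factors[:, g]
        profiles[:, 2 * g] = m
        profiles[:, 2 * g + 1] = m * act_factors
    profiles /= profiles.sum(axis=0, keepdims=True)
    prof_idx = 2 * group + act_flag.astype(int)

    lam = profiles[:, prof_idx] * libsize[None, :]
    counts = _sample_counts(rng, lam, cfg.bcv_common, cfg.bcv_df)

    gene_ids = np.array([f"G{i + 1:06d}" for i in range(G)], dtype=object)
    cell_ids = np.array([f"C{i + 1:06d}" for i in range(N)], dtype=object)
    truth = np.column_stack([group_factors, act_factors])
    names = [f"group_{g + 1}" for g in range(K)] + ["activity"]
    return SimulatedDataset(
        counts=CountMatrix(counts, gene_ids, cell_ids),
        group_label=group,
        activity_flag=act_flag,
        truth_factors=truth,
        program_names=names,
        config=cfg,
    )


def truth_gene_sets(ds: SimulatedDataset, J: int, universe=None) -> list[np.ndarray]:
    """Top-``J`` genes of each ground-truth program, ranked by |log factor|.

    Ties are broken by gene index, so programs with fewer than ``J``
    perturbed genes are padded deterministically (with a warning). When
    ``universe`` is given (e.g. the highly-variable-gene list a
    factorization was run on), ranking is restricted to those genes, so
    truth sets are comparable with programs that can only contain genes
    from that universe.
    """
    if J <= 0:
        raise ValueError("J must be positive")
    gene_ids = ds.counts.gene_ids
    factors = ds.truth_factors
    if universe is not None:
        keep = np.isin(gene_ids, np.asarray(list(universe), dtype=object))
        gene_ids, factors = gene_ids[keep], factors[keep]
    if J > len(gene_ids):
        raise ValueError("J exceeds number of genes")
    sets = []
    for p in range(ds.n_programs):
        score = np.abs(np.log(factors[:, p]))
        if int((score > 0).sum()) < J:
            warnings.warn(
                f"program {ds.program_names[p]} has fewer than {J} perturbed genes; "
                "padding by tie order"
            )
        order = np.lexsort((np.arange(len(score)), -score))
        sets.append(gene_ids[order[:J]])
    return sets


def make_gene_coords(gene_ids, n_chromosomes: int = 20, seed: int = 0) -> pd.DataFrame:
    """Synthetic genomic coordinates: genes laid out in order on pseudo-chromosomes."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    G = len(gene_ids)
    per = int(np.ceil(G / n_chromosomes))
    chrom = np.array([f"chr{i // per + 1}" for i in range(G)], dtype=object)
    start = np.array([(i % per) * 10_000 for i in range(G)])
    return pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + 1_000, "gene_id": gene_ids}
    )


def cnv_overlay(
    ds: SimulatedDataset, ccfg: CNVOverlayConfig, gene_coords: pd.DataFrame
) -> SimulatedDataset:
    """Re-draw counts with segment gains/losses in designated cancer cells.

    Cells are partitioned into cancer / ambiguous / normal roles. Cancer
    cells (and ambiguous cells when ``ambiguous_mode='as_cancer'``) have
    their expected expression multiplied by the gain/loss factor over
    ``n_segments`` contiguous genomic segments, and their counts are
    re-drawn from the perturbed rate (not post-multiplied). Normal cells
    keep their original counts.
    """
    coords = gene_coords.set_index("gene_id")
    missing = [g for g in ds.counts.gene_ids if g not in coords.index]
    if missing:
        raise ValueError(f"gene_coords missing {len(missing)} genes")
    rng = np.random.default_rng(ccfg.seed)
    G, N = ds.counts.n_genes, ds.counts.n_cells

    order = np.lexsort(
        (coords.loc[ds.counts.gene_ids, "start"].to_numpy(),
         coords.loc[ds.counts.gene_ids, "chrom"].to_numpy())
    )
    chrom_sorted = coords.loc[ds.counts.gene_ids, "chrom"].to_numpy()[order]

    # choose contiguous same-chromosome segments in genomic order
    cnv_mult = np.ones(G)
    seg_rows = []
    chroms = pd.unique(chrom_sorted)
    for s in range(ccfg.n_segments):
        ch = chroms[rng.integers(len(chroms))]
        pos = np.flatnonzero(chrom_sorted == ch)
        if len(pos) < ccfg.segment_gene_span:
            raise ValueError(f"segment span {ccfg.segment_gene_span} exceeds {ch} extent")
        lo = rng.integers(0, len(pos) - ccfg.segment_gene_span + 1)
        seg_genes = order[pos[lo : lo + ccfg.segment_gene_span]]
        # alternate gains and losses so every overlay carries both kinds
        factor = ccfg.gain_factor if s % 2 == 0 else ccfg.loss_factor
        cnv_mult[seg_genes] = factor
        seg_rows.append(
            {"segment": s, "chrom": ch, "factor": factor,
             "genes": ds.counts.gene_ids[seg_genes]}
        )

    role = np.full(N, "normal", dtype=object)
    n_cancer = int(round(ccfg.cancer_cell_frac * N))
    n_amb = int(round(ccfg.ambiguous_cell_frac * N))
    picks = rng.choice(N, size=n_cancer + n_amb, replace=False)
    role[picks[:n_cancer]] = "cancer"
    role[picks[n_cancer:]] = "ambiguous"

    affected = role == "cancer"
    if ccfg.ambiguous_mode == "as_cancer":
        affected = affected | (role == "ambiguous")

    cfg = ds.config
    counts = np.array(ds.counts.dense(), dtype=np.int32)
    if affected.any():
        # rebuild the expected rate of affected cells and re-draw
        K = cfg.n_groups
        profiles = np.empty((G, 2 * K))
        base = ds.truth_factors[:, :K] * _recover_base_mean(ds)[:, None]
        for g in range(K):
            profiles[:, 2 * g] = base[:, g]
            profiles[:, 2 * g + 1] = base[:, g] * ds.truth_factors[:, K]
        prof_idx = 2 * ds.group_label + ds.activity_flag.astype(int)
        lam = profiles[:, prof_idx[affected]] * cnv_mult[:, None]
        lam = lam / lam.sum(axis=0, keepdims=True)
        lib = counts[:, affected].sum(axis=0)
        lam = lam * lib[None, :]
        counts[:, affected] = _sample_counts(rng, lam, cfg.bcv_common, cfg.bcv_df)

    out = replace(
        ds,
        counts=CountMatrix(counts, ds.counts.gene_ids, ds.counts.cell_ids),
        role=role,
        cnv_segments=pd.DataFrame(seg_rows),
    )
    return out


def _recover_base_mean(ds: SimulatedDataset) -> np.ndarray:
    """Re-derive the per-gene base mean from the stored seed (deterministic)."""
    rng = np.random.default_rng(ds.config.seed)
    return rng.gamma(ds.config.mean_shape, 1.0 / ds.config.mean_rate, size=ds.config.n_genes)
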