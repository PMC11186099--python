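"""Program annotation: marker-set enrichment and activity summaries.

A program is annotated by asking whether a curated marker gene set sits
unusually high in the program's gene-weight ranking — a one-sided
Wilcoxon rank-sum (Mann-Whitney U) test of marker weights against all
other gene weights. Cells "highly expressing" a program are selected by
an activity threshold (h > 50 for annotation displays, h > 100 for
classifier labeling, by convention), and signature summaries report the
mean normalized expression of a gene set in those cells next to the mean
over all other genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

__all__ = [
    "MarkerGeneSet",
    "EnrichmentResult",
    "read_marker_sets",
    "ranksum_enrichment",
    "enrich_programs",
    "high_activity_cells",
    "signature_mean_expression",
    "program_coexpression",
    "lognormalize",
]


@dataclass
class MarkerGeneSet:
    name: str
    genes: tuple
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty marker set")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate marker symbols")


@dataclass
class EnrichmentResult:
    program_id: str
    set_name: str
    p_one_sided: float
    n_markers_in_universe: int
    n_markers_dropped: int
    direction: str = "greater"


def read_marker_sets(path) -> list[MarkerGeneSet]:
    """Read named marker sets from a two-column TSV (set_name, gene)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"])
    return [
        MarkerGeneSet(name=str(name), genes=tuple(dict.fromkeys(grp["gene"])))
        for name, grp in df.groupby("set_name", sort=True)
    ]


def ranksum_enrichment(
    wz_column: np.ndarray,
    gene_ids,
    markers: MarkerGeneSet,
    program_id: str = "",
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Mann-Whitney U of marker weights vs all other gene weights.

    Markers absent from the universe are dropped (and counted). The exact
    null distribution is used when the smaller group has <= 20 members and
    there are no ties; otherwise the tie-corrected normal approximation.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    in_set = np.isin(gene_ids, np.asarray(markers.genes, dtype=object))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"no marker of {markers.name!r} in the gene universe")
    if n_in == len(gene_ids):
        raise ValueError("marker set covers the whole universe")
    mw, ow = wz_column[in_set], wz_column[~in_set]
    small = min(len(mw), len(ow))
    has_ties = len(np.unique(wz_column)) < len(wz_column)
    method = "exact" if (small <= 20 and not has_ties) else "asymptotic"
    p = float(mannwhitneyu(mw, ow, alternative=alternative, method=method).pvalue)
    return EnrichmentResult(
        program_id=program_id,
        set_name=markers.name,
        p_one_sided=p,
        n_markers_in_universe=n_in,
        n_markers_dropped=len(markers.genes) - n_in,
        direction=alternative,
    )


def enrich_programs(wz: np.ndarray, gene_ids, marker_sets, program_ids=None) -> pd.DataFrame:
    """All programs x all marker sets; adds Benjamini-Hochberg q per program."""
    if program_ids is None:
        program_ids = [f"program_{i + 1}" for i in range(wz.shape[1])]
    rows = []
    for pi, pid in enumerate(program_ids):
        res = []
        for ms in marker_sets:
            try:
                res.append(ranksum_enrichment(wz[:, pi], gene_ids, ms, program_id=pid))
            except ValueError:
                continue
        ps = np.array([r.p_one_sided for r in res])
        order = np.argsort(ps)
        q = np.empty_like(ps)
        m = len(ps)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, ps[i] * m / (rank_pos + 1))
            q[i] = prev
        for r, qi in zip(res, q):
            rows.append(
                {"program_id": r.program_id, "set_name": r.set_name,
                 "p_one_sided": r.p_one_sided, "q_bh": qi,
                 "n_markers_in_universe": r.n_markers_in_universe}
            )
    return pd.DataFrame(rows)


def high_activity_cells(H: np.ndarray, program: int, h_min: float) -> np.ndarray:
    """Indices of cells with activity strictly greater than ``h_min``."""
    return np.flatnonzero(np.asarray(H)[program, :] > h_min)


def lognormalize(X: np.ndarray, target_sum: float = 10_000.0) -> np.ndarray:
    """log1p of depth-normalized counts (genes x cells)."""
    depth = X.sum(axis=0)
    depth = np.where(depth == 0, 1.0, depth)
    return np.log1p(X / depth * target_sum)


def signature_mean_expression(expr: np.ndarray, gene_ids, cells, signature) -> pd.DataFrame:
    """Per-cell mean expression of signature genes, with a background column.

    ``expr`` is a genes x cells (normalized) expression matrix; ``cells``
    indexes the cell subset of interest. The background is the per-cell
    mean over all non-signature genes — the "all other genes" box of the
    standard display.
    """
    cells = np.asarray(cells)
    if cells.size == 0:
        raise ValueError("empty cell set")
    gene_ids = np.asarray(gene_ids, dtype=object)
    in_sig = np.isin(gene_ids, np.asarray(list(signature), dtype=object))
    if not in_sig.any():
        raise ValueError("signature does not intersect the gene universe")
    sub = np.asarray(expr)[:, cells]
    return pd.DataFrame(
        {
            "cell_index": cells,
            "signature_mean": sub[in_sig].mean(axis=0),
            "background_mean": sub[~in_sig].mean(axis=0),
        }
    )


def program_coexpression(H: np.ndarray, program_ids=None) -> pd.DataFrame:
    """Spearman correlation of program activities across cells.

    Programs with constant activity get NaN off-diagonal entries (their
    rank correlation is undefined); the diagonal is 1 by convention.
    """
    H = np.asarray(H, dtype=float)
    k = H.shape[0]
    if k < 2:
        raise ValueError("need at least 2 programs")
    if program_ids is None:
        program_ids = [f"program_{i + 1}" for i in range(k)]
    corr = np.eye(k)
    const = H.std(axis=1) == 0
    for i in range(k):
        for j in range(i + 1, k):
            if const[i] or const[j]:
                corr[i, j] = corr[j, i] = np.nan
            else:
                corr[i, j] = corr[j, i] = spearmanr(H[i], H[j]).statistic
    return pd.DataFrame(corr, index=program_ids, columns=program_ids)
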