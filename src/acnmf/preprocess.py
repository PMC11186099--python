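"""Count-matrix I/O and preparation for consensus NMF.

The unit of data throughout the package is a genes x cells matrix of
non-negative values (raw UMI counts on input). Preparation for NMF follows
the consensus-NMF convention: restrict to highly variable genes selected
once on the full matrix, scale each gene to unit variance without
centering (so values stay non-negative), and split cells into two random
halves of near-equal size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "SplitPair",
    "read_counts",
    "write_counts",
    "subsample_cells",
    "select_hvg",
    "scale_for_nmf",
    "split_half",
]


@dataclass
class CountMatrix:
    """Genes x cells non-negative matrix with row/column identifiers.

    ``values`` may be dense ``ndarray`` or any scipy sparse matrix; it is
    stored as given. Use :meth:`dense` for a float ndarray view.
    """

    values: object
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if n_genes < 2 or n_cells < 2:
            raise ValueError("need at least 2 genes and 2 cells")
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell identifiers")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValueError("negative entries in count matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self, dtype=np.float64) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=dtype)
        return np.asarray(self.values, dtype=dtype)

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        vals = self.values.tocsc()[:, idx] if sp.issparse(self.values) else self.values[:, idx]
        return CountMatrix(vals, self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        vals = self.values.tocsr()[idx, :] if sp.issparse(self.values) else self.values[idx, :]
        return CountMatrix(vals, self.gene_ids[idx], self.cell_ids)


@dataclass
class SplitPair:
    """Disjoint near-equal halves of the cell index range."""

    indices_a: np.ndarray
    indices_b: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = set(self.indices_a.tolist()), set(self.indices_b.tolist())
        if a & b:
            raise ValueError("split halves overlap")
        if abs(len(a) - len(b)) > 1:
            raise ValueError("split halves differ by more than one cell")


def read_counts(path, format: str = "mtx_dir") -> CountMatrix:
    """Read a genes x cells count matrix.

    ``mtx_dir`` expects the 10x triplet convention: ``matrix.mtx`` with
    genes as rows plus ``genes.tsv`` / ``barcodes.tsv`` sidecars.
    ``dense_tsv`` expects a TSV with gene ids in the first column and cell
    ids in the header.
    """
    path = Path(path)
    if format == "mtx_dir":
        m = scipy.io.mmread(path / "matrix.mtx").tocsr()
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None).iloc[:, 0].to_numpy()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None).iloc[:, 0].to_numpy()
        if m.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {m.shape} but sidecars list {len(genes)} genes "
                f"and {len(cells)} barcodes"
            )
        return CountMatrix(m, genes, cells)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy())
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path, format: str = "mtx_dir") -> None:
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        vals = cm.values if sp.issparse(cm.values) else sp.coo_matrix(cm.values)
        scipy.io.mmwrite(str(path / "matrix.mtx"), vals)
        pd.Series(cm.gene_ids).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(cm.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "dense_tsv":
        pd.DataFrame(cm.dense(), index=cm.gene_ids, columns=cm.cell_ids).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def subsample_cells(cm: CountMatrix, max_cells: int = 50_000, seed: int = 0) -> CountMatrix:
    """Uniform subsample (without replacement) when the matrix exceeds ``max_cells``."""
    if max_cells < 2:
        raise ValueError("max_cells must be >= 2")
    if cm.n_cells <= max_cells:
        return cm
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(cm.n_cells, size=max_cells, replace=False))
    return cm.subset_cells(keep)


def select_hvg(cm: CountMatrix, n_hvg: int = 2000) -> np.ndarray:
    """Rank genes by a Fano-factor dispersion score and return the top ``n_hvg``.

    Counts are first normalized to equal per-cell depth (median depth),
    then each gene is scored by variance / mean; all-zero genes score 0.
    Returned in rank order (best first); ties broken by gene index so the
    ranking is deterministic.
    """
    if n_hvg > cm.n_genes:
        raise ValueError("n_hvg exceeds number of genes")
    X = cm.dense()
    depth = X.sum(axis=0)
    if not depth.any():
        raise ValueError("all-zero count matrix")
    depth = np.where(depth == 0, 1.0, depth)
    Xn = X / depth * np.median(depth)
    mean = Xn.mean(axis=1)
    var = Xn.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.lexsort((np.arange(cm.n_genes), -disp))
    return cm.gene_ids[order[:n_hvg]]


def scale_for_nmf(cm: CountMatrix, genes) -> tuple[np.ndarray, np.ndarray]:
    """Restrict to ``genes`` and scale each gene row to unit variance.

    No centering is applied, preserving non-negativity. Zero-variance rows
    are dropped with a warning. Returns ``(matrix, kept_gene_ids)``.
    """
    genes = np.asarray(genes, dtype=object)
    if len(genes) == 0:
        raise ValueError("empty gene list")
    pos = {g: i for i, g in enumerate(cm.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"{len(missing)} genes not in matrix (first: {missing[0]})")
    idx = np.array([pos[g] for g in genes])
    X = cm.dense()[idx, :]
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes")
    X = X[keep] / sd[keep, None]
    return X, genes[keep]


def split_half(cm_or_n, seed: int = 0) -> SplitPair:
    """Randomly split cells into two disjoint halves of near-equal size."""
    n = cm_or_n if isinstance(cm_or_n, (int, np.integer)) else cm_or_n.n_cells
    if n < 4:
        raise ValueError("need at least 4 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return SplitPair(np.sort(perm[:half]), np.sort(perm[half:]), seed=seed)
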