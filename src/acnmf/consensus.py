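"""Consensus non-negative matrix factorization of one data split.

Follows the consensus-NMF recipe: factorize the same matrix from many
random initializations, pool the basis columns from all restarts, drop the
most isolated fraction (outlier components), cluster the survivors into k
groups, and take the element-wise median of each cluster as the consensus
program. Activities are then refit per cell by non-negative least squares
against the consensus basis, and gene weights are Z-scored per program for
downstream set-overlap testing.

Two solvers are available for a single factorization: a monotone
multiplicative-update scheme (``solver='mu'``, the reference
implementation, records its full objective trajectory) and scikit-learn's
coordinate-descent/HALS solver (``solver='hals'``, several-fold faster and
used by default in the rank-selection scans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF as _SKNMF

__all__ = [
    "NMFReplicate",
    "ConsensusFactorization",
    "factorize_once",
    "run_restarts",
    "filter_outlier_components",
    "consensus_components",
    "refit_activities",
    "zscore_weights",
    "consensus_factorize",
]


@dataclass
class NMFReplicate:
    W: np.ndarray
    H: np.ndarray
    seed: int
    frobenius_error: float
    rel_error: float
    n_iter: int
    error_trajectory: np.ndarray | None = None


@dataclass
class ConsensusFactorization:
    k: int
    W_consensus: np.ndarray
    H_consensus: np.ndarray | None
    Wz: np.ndarray
    n_replicates_used: int
    kept_component_fraction: float


def _mu_nmf(X, k, rng, max_iter, tol):
    """Multiplicative updates for Frobenius loss; objective is non-increasing."""
    n, m = X.shape
    scale = np.sqrt(X.mean() / k)
    W = rng.random((n, k)) * scale + 1e-4
    H = rng.random((k, m)) * scale + 1e-4
    norm_X = np.linalg.norm(X)
    errs = []
    prev = None
    eps = 1e-12
    for it in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        err = np.linalg.norm(X - W @ H)
        errs.append(err)
        rel = err / norm_X
        if prev is not None and abs(prev - rel) < tol:
            break
        prev = rel
    return W, H, np.array(errs), it + 1


def factorize_once(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    solver: str = "mu",
) -> NMFReplicate:
    """One NMF run from a seeded random non-negative initialization."""
    X = np.asarray(X)
    if np.isnan(X).any():
        raise ValueError("NaN in input matrix")
    if not 1 <= k < min(X.shape):
        raise ValueError(f"k={k} out of range for matrix {X.shape}")
    if solver == "mu":
        rng = np.random.default_rng(seed)
        W, H, errs, n_iter = _mu_nmf(X, k, rng, max_iter, tol)
        err = float(errs[-1])
        traj = errs
    elif solver == "hals":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = _SKNMF(
                n_components=k, init="random", solver="cd", tol=tol,
                max_iter=max_iter, random_state=int(seed) % (2**31),
            )
            W = model.fit_transform(X)
            H = model.components_
        err = float(np.linalg.norm(X - W @ H))
        n_iter = model.n_iter_
        traj = None
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return NMFReplicate(
        W=W, H=H, seed=seed, frobenius_error=err,
        rel_error=err / float(np.linalg.norm(X)), n_iter=n_iter,
        error_trajectory=traj,
    )


def run_restarts(
    X: np.ndarray,
    k: int,
    n_restarts: int = 200,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    solver: str = "hals",
) -> list[NMFReplicate]:
    """Independent seeded restarts; the replicate order is deterministic."""
    if n_restarts < 2:
        raise ValueError("need at least 2 restarts")
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    return [
        factorize_once(X, k, seed=int(s), max_iter=max_iter, tol=tol, solver=solver)
        for s in seeds
    ]


def _l2_normalize_columns(W):
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    return W / norms


def filter_outlier_components(
    components: np.ndarray, rate: float = 0.10, n_neighbors: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the most isolated ``rate`` fraction of pooled basis columns.

    ``components`` is genes x n_components (columns pooled over restarts,
    L2-normalized internally). Each column is scored by its mean Euclidean
    distance to its ``n_neighbors`` nearest other columns; the top ``rate``
    fraction by score is removed. Returns (kept columns, kept indices).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    n_comp = components.shape[1]
    if n_comp < 2:
        raise ValueError("need at least 2 components")
    if n_neighbors is None:
        n_neighbors = max(1, int(round(0.3 * n_comp)))
    if n_neighbors >= n_comp:
        raise ValueError("n_neighbors must be < number of components")
    C = _l2_normalize_columns(np.asarray(components, dtype=np.float64))
    # pairwise distances via the Gram matrix of unit columns
    gram = np.clip(C.T @ C, -1.0, 1.0)
    d2 = np.maximum(2.0 - 2.0 * gram, 0.0)
    np.fill_diagonal(d2, np.inf)
    d = np.sqrt(np.sort(d2, axis=1)[:, :n_neighbors])
    score = d.mean(axis=1)
    n_drop = int(np.floor(rate * n_comp))
    if n_drop == 0:
        return C, np.arange(n_comp)
    order = np.lexsort((np.arange(n_comp), -score))
    dropped = set(order[:n_drop].tolist())
    kept_idx = np.array([i for i in range(n_comp) if i not in dropped])
    return C[:, kept_idx], kept_idx


def consensus_components(kept: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Cluster kept components into k groups; consensus = per-cluster median.

    Columns of the result are unit L2 norm, ordered by cluster size
    (descending) then lowest member index, so the output is reproducible.
    """
    if kept.shape[1] < k:
        raise ValueError(f"only {kept.shape[1]} components left for k={k}")
    C = _l2_normalize_columns(np.asarray(kept, dtype=np.float64))
    # canonical column order first, so the clustering (and hence the
    # consensus) is invariant to how the components were pooled
    canon = np.lexsort(np.round(C, 12))
    C = C[:, canon]
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(C.T)
    cols, order_keys = [], []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:  # sklearn relocates empty clusters; guard anyway
            raise RuntimeError("empty consensus cluster")
        med = np.median(C[:, members], axis=1)
        nrm = np.linalg.norm(med)
        cols.append(med / (nrm if nrm > 0 else 1.0))
        order_keys.append((-len(members), members.min()))
    order = sorted(range(k), key=lambda i: order_keys[i])
    return np.column_stack([cols[i] for i in order])


def refit_activities(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Per-cell non-negative least squares of X's columns against W.

    Solved through the Cholesky factor of W'W (k x k), so the per-cell
    problems are tiny regardless of gene count.
    """
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    k = W.shape[1]
    G = W.T @ W
    if np.linalg.matrix_rank(G) < k:
        warnings.warn("rank-deficient consensus basis; adding ridge for refit")
    L = np.linalg.cholesky(G + 1e-10 * np.eye(k))
    B = W.T @ X  # k x cells
    Z = scipy.linalg.solve_triangular(L, B, lower=True)
    H = np.empty((k, X.shape[1]))
    A = L.T
    for j in range(X.shape[1]):
        H[:, j] = scipy.optimize.nnls(A, Z[:, j])[0]
    return H


def zscore_weights(W: np.ndarray) -> np.ndarray:
    """Z-score each program's gene weights over genes."""
    W = np.asarray(W, dtype=np.float64)
    if W.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    sd = W.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance program column")
    return (W - W.mean(axis=0)) / sd


def consensus_factorize(
    X: np.ndarray,
    k: int,
    n_restarts: int = 200,
    seed: int = 0,
    outlier_rate: float = 0.10,
    max_iter: int = 200,
    tol: float = 1e-4,
    solver: str = "hals",
    refit: bool = True,
) -> ConsensusFactorization:
    """Full consensus pipeline for one data split at one rank."""
    reps = run_restarts(
        X, k, n_restarts=n_restarts, seed=seed, max_iter=max_iter, tol=tol, solver=solver
    )
    pooled = np.concatenate([r.W for r in reps], axis=1)
    # neighborhood scale follows the restart count: a real program recurs
    # about once per restart, so ~0.3 * n_restarts neighbors should be close
    kept, kept_idx = filter_outlier_components(
        pooled, rate=outlier_rate, n_neighbors=max(1, int(round(0.3 * n_restarts)))
    )
    W_cons = consensus_components(kept, k, seed=seed)
    H_cons = refit_activities(X, W_cons) if refit else None
    return ConsensusFactorization(
        k=k,
        W_consensus=W_cons,
        H_consensus=H_cons,
        Wz=zscore_weights(W_cons),
        n_replicates_used=len(reps),
        kept_component_fraction=len(kept_idx) / pooled.shape[1],
    )
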