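"""Cancer/normal classification from copy-number-like expression features.

Inferred copy number distinguishes cancer cells (aneuploid) from normal
cells (diploid) in tumor single-cell data. Rather than a full CNV caller,
the "manual features" here are per-cell averages of reference-standardized
log expression over bins of genomically consecutive genes (default 50):
a gained segment raises every bin it covers, a lost segment lowers it,
and reference (immune) cells sit near zero everywhere.

A classifier (regularized logistic regression, random forest, or a
linear-margin SVM) trained on clear cancer vs immune cells is applied to
held-out knowns (balanced accuracy), to never-trained-on endothelial
cells (estimating the misclassification rate), and to ambiguous
mesenchymal-like cells. Fisher's exact test on the resulting 2x2 table
asks whether ambiguous cells are called cancer more often than normal
endothelial cells are miscalled — the inferential design for deciding
whether an ambiguous population is cancerous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

__all__ = [
    "GenomicBinMap",
    "CellLabelSet",
    "ClassifierReport",
    "build_bins",
    "cnv_features",
    "assign_labels",
    "fit_and_predict",
    "fisher_2x2",
]


@dataclass
class GenomicBinMap:
    """Consecutive-gene bins along the genome; bins never span chromosomes."""

    bin_size: int
    bins: list  # list of (chrom, gene_id array) in genomic order

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class CellLabelSet:
    labels: np.ndarray  # per-cell in {cancer, immune, endothelial, ambiguous_mes, unlabeled}
    h_min: float
    n_conflicts: int = 0


@dataclass
class ClassifierReport:
    model_kind: str
    balanced_accuracy: float
    endothelial_prob: np.ndarray
    ambiguous_prob: np.ndarray
    contingency: np.ndarray  # [[amb cancer, amb normal], [endo cancer, endo normal]]
    fisher_p: float
    odds_ratio: float


def read_gene_coords(path) -> pd.DataFrame:
    """Read a BED-like TSV (chrom, start, end, gene_id; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"])
    if df["gene_id"].isna().any():
        raise ValueError("missing gene_id column in coordinates file")
    return df


def build_bins(gene_coords: pd.DataFrame, bin_size: int = 50) -> GenomicBinMap:
    """Bin genes sorted by (chrom, start) into runs of ``bin_size``.

    A trailing partial bin of at least ``bin_size / 2`` genes is kept;
    smaller remainders merge into the previous bin.
    """
    df = gene_coords.copy()
    if df.duplicated(subset="gene_id").any():
        raise ValueError("duplicate gene ids in coordinates")
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    bins = []
    for chrom, grp in df.groupby("chrom", sort=True):
        genes = grp["gene_id"].to_numpy(dtype=object)
        if len(genes) < bin_size and not bins:
            pass  # single short chromosome still yields one bin below
        chrom_bins = [
            genes[i : i + bin_size] for i in range(0, len(genes), bin_size)
        ]
        if len(chrom_bins) > 1 and len(chrom_bins[-1]) < bin_size / 2:
            chrom_bins[-2] = np.concatenate([chrom_bins[-2], chrom_bins[-1]])
            chrom_bins.pop()
        bins.extend((chrom, b) for b in chrom_bins)
    if not bins:
        raise ValueError("no genes to bin")
    return GenomicBinMap(bin_size=bin_size, bins=bins)


def cnv_features(
    expr: np.ndarray,
    gene_ids,
    bins: GenomicBinMap,
    reference_cells,
    clip: float = 3.0,
) -> np.ndarray:
    """Cells x bins matrix of reference-standardized binned expression.

    Per gene: log1p of depth-normalized (TPM-like) expression,
    standardized by the reference cells' mean and SD, clipped to
    [-clip, +clip]; per bin: mean over member genes present in the data.
    Genes with zero reference SD are dropped from their bin.
    """
    reference_cells = np.asarray(reference_cells)
    if reference_cells.size == 0:
        raise ValueError("reference_cells is empty")
    X = np.asarray(expr, dtype=float)
    depth = X.sum(axis=0)
    depth = np.where(depth == 0, 1.0, depth)
    L = np.log1p(X / depth * 1e4)
    mu = L[:, reference_cells].mean(axis=1)
    sd = L[:, reference_cells].std(axis=1)
    ok = sd > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} genes with zero reference SD dropped from bins")
    Z = np.zeros_like(L)
    Z[ok] = np.clip((L[ok] - mu[ok, None]) / sd[ok, None], -clip, clip)
    pos = {g: i for i, g in enumerate(np.asarray(gene_ids, dtype=object))}
    feats = np.zeros((X.shape[1], bins.n_bins))
    for bi, (_, genes) in enumerate(bins.bins):
        idx = [pos[g] for g in genes if g in pos and ok[pos[g]]]
        if idx:
            feats[:, bi] = Z[idx, :].mean(axis=0)
    return feats


def assign_labels(
    H: np.ndarray,
    program_annotations: dict,
    h_min: float = 100.0,
    program_ids=None,
) -> CellLabelSet:
    """Label cells by which annotated program they express above ``h_min``.

    ``program_annotations`` maps program id (or row index) to one of
    {cancer, immune, endothelial, ambiguous_mes}. A cell exceeding the
    threshold for programs of more than one class is left unlabeled (with
    a warning); cells exceeding no threshold are unlabeled.
    """
    H = np.asarray(H)
    if program_ids is None:
        program_ids = list(range(H.shape[0]))
    index = {pid: i for i, pid in enumerate(program_ids)}
    classes = ("cancer", "immune", "endothelial", "ambiguous_mes")
    for pid, cls in program_annotations.items():
        if pid not in index:
            raise ValueError(f"annotation references unknown program {pid!r}")
        if cls not in classes:
            raise ValueError(f"unknown class {cls!r}")
    labels = np.full(H.shape[1], "unlabeled", dtype=object)
    n_conflicts = 0
    for j in range(H.shape[1]):
        hit = {
            cls for pid, cls in program_annotations.items()
            if H[index[pid], j] > h_min
        }
        if len(hit) == 1:
            labels[j] = hit.pop()
        elif len(hit) > 1:
            n_conflicts += 1
    if n_conflicts:
        warnings.warn(f"{n_conflicts} cells passed thresholds for multiple classes")
    return CellLabelSet(labels=labels, h_min=h_min, n_conflicts=n_conflicts)


def _make_model(model_kind: str, seed: int):
    if model_kind == "regularized-logistic":
        return LogisticRegression(max_iter=2000, C=1.0, random_state=seed)
    if model_kind == "random-forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if model_kind == "linear-margin":
        return LinearSVC(C=1.0, random_state=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _predict_prob(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    # linear-margin: squash the decision margin so a 0.5 cut = the margin sign
    return 1.0 / (1.0 + np.exp(-model.decision_function(X)))


def fit_and_predict(
    features: np.ndarray,
    labels: np.ndarray,
    model_kind: str = "regularized-logistic",
    train_frac: float = 0.75,
    seed: int = 0,
) -> ClassifierReport:
    """Train cancer-vs-normal on cancer + immune cells; score the rest.

    Cancer cells are split ``train_frac`` / held-out (as are immune cells,
    so specificity is estimable); endothelial cells are never trained on
    and estimate the misclassification rate; ambiguous cells receive
    probabilities and classes (0.5 cut). Balanced accuracy =
    (sensitivity + specificity) / 2 on the held-out knowns. The Fisher
    test compares cancer-call rates between ambiguous and endothelial
    cells.
    """
    labels = np.asarray(labels, dtype=object)
    features = np.asarray(features, dtype=float)
    idx = {c: np.flatnonzero(labels == c) for c in
           ("cancer", "immune", "endothelial", "ambiguous_mes")}
    if len(idx["cancer"]) < 20 or len(idx["immune"]) < 20:
        raise ValueError("need at least 20 cancer and 20 immune cells")
    rng = np.random.default_rng(seed)

    def split(ix):
        perm = rng.permutation(len(ix))
        n_train = int(round(train_frac * len(ix)))
        return ix[perm[:n_train]], ix[perm[n_train:]]

    ca_tr, ca_te = split(idx["cancer"])
    im_tr, im_te = split(idx["immune"])
    X_tr = features[np.concatenate([ca_tr, im_tr])]
    y_tr = np.r_[np.ones(len(ca_tr)), np.zeros(len(im_tr))]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("single-class training set")
    model = _make_model(model_kind, seed)
    model.fit(X_tr, y_tr)

    sens = float((_predict_prob(model, features[ca_te]) > 0.5).mean()) if len(ca_te) else np.nan
    spec = float((_predict_prob(model, features[im_te]) <= 0.5).mean()) if len(im_te) else np.nan
    bal_acc = (sens + spec) / 2.0

    endo_p = _predict_prob(model, features[idx["endothelial"]]) if len(idx["endothelial"]) else np.array([])
    amb_p = _predict_prob(model, features[idx["ambiguous_mes"]]) if len(idx["ambiguous_mes"]) else np.array([])
    a = int((amb_p > 0.5).sum())
    b = int((amb_p <= 0.5).sum())
    c = int((endo_p > 0.5).sum())
    d = int((endo_p <= 0.5).sum())
    if min(a + c, b + d, a + b, c + d) == 0:
        # degenerate margin (e.g. nobody called cancer): no evidence of a
        # rate difference
        orat, p = np.nan, 1.0
    else:
        orat, p = fisher_2x2(a, b, c, d)
    return ClassifierReport(
        model_kind=model_kind,
        balanced_accuracy=bal_acc,
        endothelial_prob=endo_p,
        ambiguous_prob=amb_p,
        contingency=np.array([[a, b], [c, d]]),
        fisher_p=p,
        odds_ratio=orat,
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test (two-sided, minimum-likelihood convention).

    Returns ``(conditional MLE odds ratio, p)``. The p-value sums the
    hypergeometric probabilities of all tables (with the observed margins)
    no more likely than the observed one.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("negative cell count")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    _, p = fisher_exact(table, alternative="two-sided")
    orat = odds_ratio(table, kind="conditional").statistic
    return float(orat), float(p)
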