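import numpy as np
import pandas as pd
import pytest
from math import comb

from acnmf.cnv import (
    assign_labels,
    build_bins,
    cnv_features,
    fisher_2x2,
    fit_and_predict,
)
from acnmf.simulate import CNVOverlayConfig, cnv_overlay, make_gene_coords


def coords_frame(n, per_chrom=None):
    genes = [f"g{i:04d}" for i in range(n)]
    if per_chrom is None:
        chrom = ["chr1"] * n
    else:
        chrom = [f"chr{i // per_chrom + 1}" for i in range(n)]
    return pd.DataFrame(
        {"chrom": chrom, "start": [i * 100 for i in range(n)],
         "end": [i * 100 + 50 for i in range(n)], "gene_id": genes}
    )


class TestBuildBins:
    def test_even_split(self):
        bm = build_bins(coords_frame(100), bin_size=50)
        assert [len(b) for _, b in bm.bins] == [50, 50]

    def test_trailing_partial_merged(self):
        bm = build_bins(coords_frame(120), bin_size=50)
        assert [len(b) for _, b in bm.bins] == [50, 70]

    def test_trailing_partial_kept_when_large(self):
        bm = build_bins(coords_frame(130), bin_size=50)
        assert [len(b) for _, b in bm.bins] == [50, 50, 30]

    def test_shuffled_input_same_bins(self, rng):
        df = coords_frame(150, per_chrom=75)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, b = build_bins(df), build_bins(shuffled)
        assert all(np.array_equal(x[1], y[1]) for x, y in zip(a.bins, b.bins))

    def test_bins_never_span_chromosomes(self):
        bm = build_bins(coords_frame(200, per_chrom=60), bin_size=50)
        for chrom, genes in bm.bins:
            assert len(genes) <= 70
            assert len({chrom}) == 1

    def test_duplicate_genes_raise(self):
        df = coords_frame(60)
        df.loc[1, "gene_id"] = df.loc[0, "gene_id"]
        with pytest.raises(ValueError, match="duplicate"):
            build_bins(df)


class TestCNVFeatures:
    def test_reference_like_cells_near_zero(self, rng):
        G, N = 200, 60
        X = rng.poisson(20.0, (G, N)).astype(float)
        genes = [f"g{i:04d}" for i in range(G)]
        bm = build_bins(coords_frame(G), bin_size=50)
        feats = cnv_features(X, genes, bm, reference_cells=np.arange(30))
        nonref = feats[30:]
        assert np.abs(nonref.mean()) < 0.1
        assert np.abs(nonref).mean() < 0.5

    def test_clipping_rule(self, rng):
        G, N = 100, 40
        X = rng.poisson(20.0, (G, N)).astype(float)
        X[3, 39] *= 100.0  # single-gene outlier cannot dominate its bin
        genes = [f"g{i:04d}" for i in range(G)]
        bm = build_bins(coords_frame(G), bin_size=50)
        feats = cnv_features(X, genes, bm, reference_cells=np.arange(30))
        assert feats[39, 0] <= (3.0 + 49 * 3.0) / 50  # every gene capped at +3

    def test_gain_segment_raises_covering_bin(self, small_sim):
        coords = make_gene_coords(small_sim.counts.gene_ids, n_chromosomes=8)
        ccfg = CNVOverlayConfig(
            n_segments=3, segment_gene_span=60, cancer_cell_frac=0.4,
            ambiguous_cell_frac=0.0, seed=2,
        )
        ds = cnv_overlay(small_sim, ccfg, coords)
        bm = build_bins(coords, bin_size=50)
        ref = np.flatnonzero(ds.role == "normal")[:120]
        feats = cnv_features(ds.counts.dense(), ds.counts.gene_ids, bm, ref)
        cancer = ds.role == "cancer"
        seg_genes = set(np.concatenate(ds.cnv_segments["genes"].to_list()))
        gains = set()
        for _, row in ds.cnv_segments.iterrows():
            if row["factor"] > 1:
                gains |= set(row["genes"])
        deltas = []
        for bi, (_, genes) in enumerate(bm.bins):
            frac_gain = np.mean([g in gains for g in genes])
            clean = not any(g in seg_genes for g in genes)
            if frac_gain > 0.6:
                deltas.append(
                    feats[cancer, bi].mean()
                )
            elif clean:
                deltas.append(None)
        gain_scores = [d for d in deltas if d is not None]
        assert gain_scores and min(gain_scores) > 0.1


class TestAssignLabels:
    def test_no_cell_above_threshold(self):
        H = np.zeros((2, 5))
        ls = assign_labels(H, {0: "cancer", 1: "immune"}, h_min=100)
        assert set(ls.labels) == {"unlabeled"}

    def test_conflicting_cell_unlabeled_with_warning(self):
        H = np.array([[150.0, 10.0], [150.0, 120.0]])
        with pytest.warns(UserWarning, match="multiple classes"):
            ls = assign_labels(H, {0: "cancer", 1: "immune"}, h_min=100)
        assert ls.labels[0] == "unlabeled"
        assert ls.labels[1] == "immune"
        assert ls.n_conflicts == 1

    def test_planted_identities_recovered(self, rng):
        n = 300
        truth = rng.choice(["cancer", "immune", "endothelial"], n)
        H = np.zeros((3, n))
        for i, cls in enumerate(["cancer", "immune", "endothelial"]):
            H[i, truth == cls] = 200.0
        ls = assign_labels(H, {0: "cancer", 1: "immune", 2: "endothelial"}, h_min=100)
        assert (ls.labels == truth).mean() >= 0.99

    def test_unknown_program_raises(self):
        with pytest.raises(ValueError, match="unknown program"):
            assign_labels(np.zeros((1, 3)), {5: "cancer"})


class TestFitAndPredict:
    def make_separable(self, rng, n_per=60, p=10, shift=4.0):
        feats = rng.normal(size=(4 * n_per, p))
        labels = np.array(
            ["cancer"] * n_per + ["immune"] * n_per
            + ["endothelial"] * n_per + ["ambiguous_mes"] * n_per, dtype=object
        )
        feats[:n_per, 0] += shift  # cancer separated on one feature
        return feats, labels

    def test_perfect_feature_gives_balanced_accuracy_one(self, rng):
        feats, labels = self.make_separable(rng, shift=8.0)
        rep = fit_and_predict(feats, labels, seed=1)
        assert rep.balanced_accuracy == 1.0
        # normals stay normal, so the 2x2 stays balanced and p is large
        assert rep.fisher_p > 0.05

    def test_permuted_labels_near_chance(self, rng):
        feats, labels = self.make_separable(rng, shift=0.0)
        rep = fit_and_predict(feats, labels, seed=2)
        # 15 held-out cancer + 15 held-out immune; binomial 99% band around 0.5
        assert 0.2 <= rep.balanced_accuracy <= 0.8

    def test_cancer_like_ambiguous_cells_are_flagged(self, rng):
        feats, labels = self.make_separable(rng, shift=6.0)
        feats[labels == "ambiguous_mes", 0] += 6.0  # ambiguous look like cancer
        rep = fit_and_predict(feats, labels, seed=3)
        assert rep.fisher_p < 0.01
        assert rep.contingency[0, 0] > rep.contingency[1, 0]

    def test_model_kinds_agree_on_separable_data(self, rng):
        feats, labels = self.make_separable(rng, shift=8.0)
        calls = []
        for kind in ("regularized-logistic", "random-forest", "linear-margin"):
            rep = fit_and_predict(feats, labels, model_kind=kind, seed=4)
            calls.append(np.r_[rep.endothelial_prob > 0.5, rep.ambiguous_prob > 0.5])
        agree01 = np.mean(calls[0] == calls[1])
        agree02 = np.mean(calls[0] == calls[2])
        assert min(agree01, agree02) >= 0.9

    def test_determinism_and_minimum_counts(self, rng):
        feats, labels = self.make_separable(rng)
        r1 = fit_and_predict(feats, labels, seed=9)
        r2 = fit_and_predict(feats, labels, seed=9)
        np.testing.assert_array_equal(r1.contingency, r2.contingency)
        with pytest.raises(ValueError, match="at least 20"):
            fit_and_predict(feats[:30], labels[:30])


class TestFisher2x2:
    def test_balanced_table(self):
        orat, p = fisher_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0)
        assert orat == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        _, p = fisher_2x2(10, 0, 0, 10)
        expected = 2 * comb(10, 10) * comb(10, 0) / comb(20, 10)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_transpose_symmetry(self):
        _, p1 = fisher_2x2(7, 2, 3, 8)
        _, p2 = fisher_2x2(7, 3, 2, 8)  # simultaneous row & column swap
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_2x2(0, 0, 3, 4)
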