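import itertools
from math import comb

import networkx as nx
import numpy as np
import pytest
from scipy.stats import kstest

from acnmf.rank_select import (
    CommunityCurve,
    ProgramSet,
    count_communities,
    find_inflection,
    jaccard_test,
    loess_smooth,
    match_split_programs,
    match_to_truth,
    scan,
    select_jaccard_length,
    top_genes,
)
from acnmf.consensus import zscore_weights


def hypergeom_tail_bruteforce(G, na, nb, x):
    """Exact P(|A & B| >= x) for independent fixed-size draws, by tail sum."""
    total = comb(G, nb)
    return sum(comb(na, i) * comb(G - na, nb - i) for i in range(x, min(na, nb) + 1)) / total


def set_to_programset(sets, universe):
    """Build a ProgramSet whose top-|s| Z-scored genes are exactly the given sets."""
    universe = np.asarray(universe, dtype=object)
    W = np.zeros((len(universe), len(sets)))
    pos = {g: i for i, g in enumerate(universe)}
    rng = np.random.default_rng(0)
    W += rng.random(W.shape) * 1e-3
    for j, s in enumerate(sets):
        for g in s:
            W[pos[g], j] = 1.0 + rng.random()
    return ProgramSet(
        program_ids=[f"p{j}" for j in range(len(sets))],
        gene_ids=universe,
        gene_weights=W,
        wz=zscore_weights(W),
        activities=None,
        member_nodes=[[] for _ in sets],
    )


class TestTopGenes:
    def test_ranking(self):
        got = top_genes(np.array([3.0, 1.0, 2.0]), 2, ["a", "b", "c"])
        assert set(got) == {"a", "c"}

    def test_all_genes(self):
        assert len(top_genes(np.arange(5.0), 5, list("abcde"))) == 5

    def test_tie_break_lexicographic(self):
        got = top_genes(np.array([1.0, 0.5, 0.5, 0.5]), 2, ["d", "c", "b", "a"])
        assert list(got) == ["d", "a"]

    def test_invalid_J(self):
        with pytest.raises(ValueError):
            top_genes(np.ones(3), 0, list("abc"))


class TestJaccardTest:
    def test_identical_sets(self):
        A = set(range(10))
        res = jaccard_test(A, A, 100)
        assert res.jaccard_index == 1.0
        assert res.p_raw == pytest.approx(1.0 / comb(100, 10) * comb(90, 0) * comb(10, 10))

    def test_disjoint_sets(self):
        res = jaccard_test(set(range(5)), set(range(5, 10)), 100)
        assert res.jaccard_index == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_matches_bruteforce_tail(self):
        res = jaccard_test(set(range(10)), set(range(5, 15)), 100)
        assert res.intersection == 5
        assert res.p_raw == pytest.approx(hypergeom_tail_bruteforce(100, 10, 10, 5), rel=1e-12)

    def test_universe_too_small(self):
        with pytest.raises(ValueError, match="universe"):
            jaccard_test({1, 2}, {3, 4}, 3)

    def test_null_pvalues_superuniform(self, rng):
        """Random same-size draws: p-values stochastically >= uniform."""
        G, J = 200, 15
        ps = []
        for _ in range(400):
            A = frozenset(rng.choice(G, J, replace=False).tolist())
            B = frozenset(rng.choice(G, J, replace=False).tolist())
            ps.append(jaccard_test(A, B, G).p_raw)
        stat = kstest(ps, "uniform", alternative="greater")
        assert stat.pvalue > 0.01


class TestMatchSplitPrograms:
    def make_wz(self, rng, G, k):
        return zscore_weights(rng.gamma(2.0, 1.0, (G, k)))

    def test_permuted_twin_perfect_matching(self, rng):
        G, k = 300, 6
        genes = np.array([f"g{i}" for i in range(G)], dtype=object)
        Wz = self.make_wz(rng, G, k)
        perm = rng.permutation(k)
        edges = match_split_programs(Wz, Wz[:, perm], genes, J=20)
        assert len(edges) == k
        assert {(i, j) for i, j, _ in edges} == {(perm[j], j) for j in range(k)}

    def test_shuffled_null_edge_count_bounded(self, rng):
        G, k = 300, 6
        genes = np.array([f"g{i}" for i in range(G)], dtype=object)
        Wz_a = self.make_wz(rng, G, k)
        Wz_b = self.make_wz(rng, G, k)[rng.permutation(G), :]
        edges = match_split_programs(Wz_a, Wz_b, genes, J=20, alpha=0.05)
        # Bonferroni controls FWER at 0.05: more than 2 false edges is wild
        assert len(edges) <= 2

    def test_single_identical_column(self, rng):
        genes = np.array([f"g{i}" for i in range(100)], dtype=object)
        Wz = self.make_wz(rng, 100, 1)
        edges = match_split_programs(Wz, Wz, genes, J=10)
        assert len(edges) == 1


def all_partitions(nodes):
    nodes = list(nodes)
    if len(nodes) == 1:
        yield [nodes]
        return
    first = nodes[0]
    for smaller in all_partitions(nodes[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
        yield [[first]] + smaller


def bruteforce_max_modularity(graph):
    best_q, best_n = -np.inf, 0
    for part in all_partitions(sorted(graph.nodes)):
        q = nx.community.modularity(graph, [set(p) for p in part])
        if q > best_q + 1e-12:
            best_q, best_n = q, len(part)
    return best_n


class TestCountCommunities:
    def test_empty(self):
        assert count_communities([]) == (0, [])

    def test_two_disjoint_edges(self):
        n, _ = count_communities([(1, 2), (3, 4)])
        assert n == 2

    def test_two_cliques_with_bridge(self):
        edges = list(itertools.combinations(range(4), 2))
        edges += list(itertools.combinations(range(4, 8), 2))
        edges.append((0, 4))
        g = nx.Graph(edges)
        n, part = count_communities(edges)
        assert n == bruteforce_max_modularity(g) == 2


class TestLoess:
    def test_reproduces_line(self):
        x = np.arange(2, 12, dtype=float)
        pts = list(zip(x, 3.0 * x - 1.0))
        np.testing.assert_allclose(loess_smooth(pts), 3.0 * x - 1.0, atol=1e-6)

    def test_constant(self):
        pts = [(k, 5.0) for k in range(8)]
        np.testing.assert_allclose(loess_smooth(pts), 5.0, atol=1e-8)

    def test_noisy_concave_within_envelope(self, rng):
        x = np.linspace(0, 10, 40)
        truth = -((x - 6.0) ** 2) / 8.0 + 5.0
        noise = rng.normal(0, 0.15, size=(3, 40))
        pts = [(xi, truth[i] + noise[r, i]) for r in range(3) for i, xi in enumerate(x)]
        sm = loess_smooth(pts, span=0.5, grid=x)
        assert np.max(np.abs(sm - truth)) < 0.45  # 3 sigma of the noise

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            loess_smooth([(0, 1), (1, 2), (2, 3)])


class TestFindInflection:
    def test_bilinear_elbow(self):
        pts = [(1, 1), (2, 2), (3, 3), (4, 3), (5, 3)]
        k_star, residuals, degenerate = find_inflection(pts)
        assert k_star == 3 and not degenerate

    def test_linear_degenerate(self):
        pts = [(k, 2.0 * k) for k in range(1, 6)]
        k_star, residuals, degenerate = find_inflection(pts)
        assert degenerate
        assert max(r for _, r in residuals) < 1e-9

    def test_min_curve_breakpoint(self):
        ks = np.arange(2, 41)
        pts = [(k, min(k, 14)) for k in ks]
        k_star, _, _ = find_inflection(pts)
        assert k_star == 14


class TestSelectJaccardLength:
    def make_curve(self, J, slope):
        c = CommunityCurve(jaccard_length=J, points=[])
        c.post_inflection_slope = slope
        return c

    def test_closest_to_minus_one(self):
        a, b = self.make_curve(10, -1.0), self.make_curve(20, -0.4)
        assert select_jaccard_length([a, b]) == 10

    def test_single_candidate_warns(self):
        with pytest.warns(UserWarning, match="single candidate"):
            assert select_jaccard_length([self.make_curve(30, -0.2)]) == 30

    def test_known_slopes_from_ols(self):
        """Curves built from synthetic cost series with known slopes -1.3/-0.9/-0.2."""
        curves = []
        for J, slope in ((10, -1.3), (20, -0.9), (50, -0.2)):
            xs = np.linspace(0.5, 1.0, 6)
            c = CommunityCurve(jaccard_length=J, points=[])
            c.cost_points = list(zip(xs, slope * xs + 2.0))
            c.post_inflection_slope = float(np.polyfit(xs, slope * xs + 2.0, 1)[0])
            curves.append(c)
        assert select_jaccard_length(curves) == 20


class TestScan:
    def test_determinism_and_structure(self, small_sim):
        kwargs = dict(
            k_grid=(3, 4, 5, 6), J_grid=(10,), n_reps=1, seed=5,
            n_hvg=300, n_restarts=4, max_iter=50,
        )
        c1 = scan(small_sim.counts, **kwargs)
        c2 = scan(small_sim.counts, **kwargs)
        assert [c.points for c in c1] == [c.points for c in c2]
        assert all(n >= 0 for _, _, n in c1[0].points)

    def test_J_exceeding_universe_raises(self, small_sim):
        with pytest.raises(ValueError, match="Jaccard length"):
            scan(small_sim.counts, (3, 4, 5, 6), (5000,), n_reps=1, seed=0, n_hvg=300)


class TestMatchToTruth:
    def test_programs_equal_truth_all_matched(self, rng):
        universe = np.array([f"g{i}" for i in range(200)], dtype=object)
        sets = [frozenset(universe[i * 10 : (i + 1) * 10]) for i in range(5)]
        ps = set_to_programset(sets, universe)
        assert match_to_truth(ps, sets, 10) == 5

    def test_shuffled_programs_match_nothing(self, rng):
        universe = np.array([f"g{i}" for i in range(200)], dtype=object)
        truth = [frozenset(rng.choice(universe, 10, replace=False)) for _ in range(5)]
        other = [frozenset(rng.choice(universe, 10, replace=False)) for _ in range(5)]
        ps = set_to_programset(other, universe)
        assert match_to_truth(ps, truth, 10) <= 1

    def test_partial_coverage_counts(self):
        universe = np.array([f"g{i}" for i in range(200)], dtype=object)
        sets = [frozenset(universe[i * 10 : (i + 1) * 10]) for i in range(14)]
        ps = set_to_programset(sets[:13], universe)
        assert match_to_truth(ps, sets, 10) == 13
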