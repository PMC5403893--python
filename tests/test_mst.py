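"""Kruskal MST construction and the tree metric suite."""

import math

import numpy as np
import pytest

from conftest import path_tree, random_pli_matrix, random_spanning_tree, star_tree
from plinet import (
    SpanningTree,
    build_mst,
    mst_betweenness,
    mst_degree,
    mst_degree_correlation,
    mst_distance_metrics,
    mst_kappa,
    mst_leaf_number,
    mst_metrics,
    mst_tree_hierarchy,
)

from _oracles import (
    all_spanning_trees,
    bf_betweenness_counts,
    bf_eccentricity,
    bf_pearson,
    tree_path,
)


class TestBuildMst:
    def test_weakest_cycle_edge_dropped(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.8
        tree = build_mst(w)
        assert {(i, j) for i, j, _ in tree.edges} == {(0, 1), (1, 2)}

    def test_tree_property(self, rng):
        w = random_pli_matrix(rng, 15)
        tree = build_mst(w)
        assert len(tree.edges) == 14  # SpanningTree validates acyclicity

    def test_exhaustive_seven_node_optimality(self, rng):
        # oracle: minimum total 1/w over all 7^5 labeled trees
        trees = list(all_spanning_trees(7))
        for _ in range(10):
            w = random_pli_matrix(rng, 7)
            best = min(
                sum(1.0 / w[i, j] for i, j in t) for t in trees
            )
            got = sum(1.0 / wt for _, _, wt in build_mst(w).edges)
            assert got == pytest.approx(best, rel=1e-12)

    def test_monotone_transform_leaves_edges_unchanged(self, rng):
        w = random_pli_matrix(rng, 12)
        edges = {(i, j) for i, j, _ in build_mst(w).edges}
        transformed = {(i, j) for i, j, _ in build_mst(w**3 + 0.2 * w).edges}
        assert edges == transformed

    def test_tie_breaking_is_deterministic(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        tree = build_mst(w)
        assert [(i, j) for i, j, _ in tree.edges] == [(0, 1), (0, 2), (0, 3)]

    def test_disconnected_graph_lists_components(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.9
        w[2, 3] = w[3, 2] = 0.8
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            build_mst(w)


class TestTreeMetrics:
    def test_star_closed_forms(self):
        n = 8
        tree = star_tree(n)
        deg, frac = mst_degree(tree)
        assert deg[0] == n - 1 and np.all(deg[1:] == 1)
        assert frac[0] == pytest.approx((n - 1) / (2 * (n - 1)))
        bc = mst_betweenness(tree)
        assert bc[0] == pytest.approx(1.0) and np.all(bc[1:] == 0.0)
        ecc, diameter = mst_distance_metrics(tree)
        assert ecc[0] == 1 and np.all(ecc[1:] == 2) and diameter == 2
        assert mst_leaf_number(tree) == n - 1
        assert mst_degree_correlation(tree) == pytest.approx(-1.0)
        assert mst_tree_hierarchy(tree) == pytest.approx(0.5)

    def test_path_closed_forms(self):
        n = 9
        tree = path_tree(n)
        deg, _ = mst_degree(tree)
        assert sorted(deg) == [1, 1] + [2] * (n - 2)
        assert mst_leaf_number(tree) == 2
        _, diameter = mst_distance_metrics(tree)
        assert diameter == n - 1
        kappa, _ = mst_kappa(tree)
        assert kappa == pytest.approx((4 * n - 6) / (2 * n - 2))

    def test_path_middle_betweenness_by_enumeration(self):
        tree = path_tree(5)
        bc = mst_betweenness(tree)
        assert bc[2] == pytest.approx(4 / 6)

    def test_star4_kappa_hand_computed(self):
        kappa, hist = mst_kappa(star_tree(4))
        assert kappa == pytest.approx(2.0)
        assert hist == {1: 0.75, 3: 0.25}

    def test_degree_sum_handshake(self, rng):
        for n in (4, 7, 11):
            tree = random_spanning_tree(rng, n)
            deg, frac = mst_degree(tree)
            assert deg.sum() == 2 * (n - 1)
            assert frac.sum() == pytest.approx(1.0)

    def test_zero_variance_degree_correlation_flagged(self):
        # triangle-free 2-node path: both endpoint degrees equal 1
        tree = SpanningTree(n_nodes=2, edges=[(0, 1, 0.5)])
        assert math.isnan(mst_degree_correlation(tree))

    def test_metrics_against_brute_force_oracles(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            tree = random_spanning_tree(rng, n)
            edges = [(i, j) for i, j, _ in tree.edges]
            pairs = (n - 1) * (n - 2) / 2
            counts = bf_betweenness_counts(edges, n)
            assert np.allclose(mst_betweenness(tree), counts / pairs)
            assert np.array_equal(
                mst_distance_metrics(tree)[0], bf_eccentricity(edges, n)
            )
            deg = tree.degrees()
            assert mst_leaf_number(tree) == int((deg == 1).sum())
            x = [deg[i] for i, j in edges] + [deg[j] for i, j in edges]
            y = [deg[j] for i, j in edges] + [deg[i] for i, j in edges]
            r = mst_degree_correlation(tree)
            if not math.isnan(r):
                assert r == pytest.approx(bf_pearson(x, y))
            kappa, _ = mst_kappa(tree)
            assert kappa == pytest.approx(
                np.mean(np.array(deg) ** 2) / np.mean(deg)
            )
            th = mst_tree_hierarchy(tree)
            bc_max = counts.max() / pairs
            assert th == pytest.approx(
                (deg == 1).sum() / (2 * (n - 1) * bc_max)
            )

    def test_passthrough_count_identity(self, rng):
        # sum of raw pass-through counts == sum over pairs of (hops - 1)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            edges = [(i, j) for i, j, _ in random_spanning_tree(rng, n).edges]
            counts = bf_betweenness_counts(edges, n)
            total_hops = sum(
                len(tree_path(edges, n, s, t)) - 2
                for s in range(n)
                for t in range(s + 1, n)
            )
            assert counts.sum() == total_hops

    def test_hierarchy_bounded_on_all_six_node_trees(self):
        for edges in all_spanning_trees(6):
            tree = SpanningTree(
                n_nodes=6, edges=[(min(e), max(e), 0.5) for e in edges]
            )
            assert 0.0 < mst_tree_hierarchy(tree) <= 1.0

    def test_bundle_invariants_on_random_trees(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            m = mst_metrics(random_spanning_tree(rng, n))
            assert m.degree.sum() == 2 * (n - 1)
            assert 2 <= m.leaf_number <= n - 1
            assert m.diameter == m.eccentricity.max()
            assert m.bc_max == m.bc.max()
            assert np.all((m.bc >= 0) & (m.bc <= 1))
            assert m.kappa >= 1.0
            assert 0.0 < m.tree_hierarchy <= 1.0
            assert sum(m.degree_histogram.values()) == pytest.approx(1.0)

    def test_invalid_edge_count_rejected(self):
        with pytest.raises(ValueError, match="edges"):
            SpanningTree(n_nodes=4, edges=[(0, 1, 0.5), (2, 3, 0.5)])
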