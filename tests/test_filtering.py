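"""Filtering tests: ranking determinism, density thresholds, ECO, MST,
PMFG and the MST+ECO hybrid."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from econet import (
    BinaryGraph,
    WeightedConnectome,
    density,
    eco_filter,
    er_random,
    local_efficiency,
    mst_eco_filter,
    mst_filter,
    planted_connectome,
    pmfg_filter,
    rank_links,
    threshold_by_density,
    threshold_by_weight,
)


def symmetric(w):
    w = np.asarray(w, dtype=float)
    return WeightedConnectome((w + w.T) / 2)


def random_connectome(n, seed):
    r = np.random.default_rng(seed)
    w = r.random((n, n))
    return symmetric(w)


class TestConnectomeType:
    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            WeightedConnectome(np.zeros((3, 4)))

    def test_rejects_asymmetric_undirected(self):
        w = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            WeightedConnectome(w)
        WeightedConnectome(w, directed=True)  # fine when declared directed

    def test_diagonal_zeroed(self):
        w = WeightedConnectome(np.eye(3) * 5 + 1 - np.eye(3))
        assert np.all(np.diag(w.weights) == 0)


class TestRankLinks:
    def test_descending_with_index_tie_break(self):
        w = symmetric([[0, 0.9, 0.5], [0.9, 0, 0.5], [0.5, 0.5, 0]])
        r = rank_links(w)
        assert r.pairs == ((0, 1), (0, 2), (1, 2))

    def test_all_equal_weights_lexicographic(self):
        w = symmetric(np.ones((4, 4)))
        r = rank_links(w)
        assert r.pairs == ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

    def test_absolute_mode_ranks_by_magnitude(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = -0.8
        m[0, 2] = m[2, 0] = 0.5
        r = rank_links(WeightedConnectome(m), mode="absolute")
        assert r.pairs[0] == (0, 1) and r.pairs[1] == (0, 2)
        assert rank_links(WeightedConnectome(m), mode="raw").pairs[0] == (0, 2)

    def test_non_finite_weights_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValueError):
            rank_links(WeightedConnectome(m))

    def test_covers_all_candidate_pairs(self):
        w = random_connectome(6, 0)
        assert len(rank_links(w)) == 15


class TestThresholdByDensity:
    def test_half_density_four_nodes(self):
        w = random_connectome(4, 1)
        g = threshold_by_density(w, 0.5)
        assert g.m == 3
        top = set(rank_links(w).pairs[:3])
        assert g.links == frozenset(top)

    def test_extremes(self):
        w = random_connectome(5, 2)
        assert threshold_by_density(w, 0.0).m == 0
        assert threshold_by_density(w, 1.0).m == 10

    def test_out_of_range_density(self):
        with pytest.raises(ValueError):
            threshold_by_density(random_connectome(4, 3), 1.5)

    @given(st.integers(0, 100), st.integers(0, 100))
    def test_nested_thresholds(self, a, b):
        """links(rho1) is a subset of links(rho2) whenever rho1 < rho2."""
        w = random_connectome(8, 17)
        r1, r2 = sorted((a / 100, b / 100))
        g1 = threshold_by_density(w, r1)
        g2 = threshold_by_density(w, r2)
        assert g1.links <= g2.links

    def test_planted_recovery(self, rng):
        for seed in range(5):
            g = er_random(15, 0.3, seed=seed)
            w = planted_connectome(g, signal_low=0.5, noise_high=0.3, seed=seed)
            assert threshold_by_density(w, density(g)) == g


class TestThresholdByWeight:
    def test_keeps_links_at_or_above_cutoff(self):
        w = symmetric([[0, 0.9, 0.2], [0.9, 0, 0.5], [0.2, 0.5, 0]])
        g = threshold_by_weight(w, 0.5)
        assert g.links == frozenset({(0, 1), (1, 2)})

    def test_absolute_mode(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = -0.8
        m[0, 2] = m[2, 0] = 0.5
        g = threshold_by_weight(WeightedConnectome(m), 0.6, mode="absolute")
        assert g.links == frozenset({(0, 1)})


class TestEcoFilter:
    @pytest.mark.parametrize("n,expected_m", [(90, 135), (61, 92), (4, 6)])
    def test_link_counts(self, n, expected_m):
        w = random_connectome(n, n)
        assert eco_filter(w).m == expected_m

    def test_equals_density_threshold_at_three(self):
        w = random_connectome(40, 5)
        assert eco_filter(w) == threshold_by_density(w, 3 / 39)

    def test_too_small_network(self):
        with pytest.raises(ValueError):
            eco_filter(random_connectome(2, 0))

    def test_warns_on_insufficient_nonzero_weights(self):
        m = np.zeros((10, 10))
        m[0, 1] = m[1, 0] = 1.0
        with pytest.warns(UserWarning):
            eco_filter(WeightedConnectome(m))

    def test_directed_keeps_three_n_arcs(self):
        r = np.random.default_rng(8)
        w = WeightedConnectome(r.random((20, 20)), directed=True)
        g = eco_filter(w)
        assert g.directed and g.m == 60


class TestMstFilter:
    def test_greedy_max_weight_triangle(self):
        w = symmetric([[0, 3, 1], [3, 0, 2], [1, 2, 0]])
        t = mst_filter(w)
        assert t.links == frozenset({(0, 1), (1, 2)})

    def test_matches_networkx_maximum_spanning_tree_weight(self):
        w = random_connectome(12, 9)
        t = mst_filter(w)
        G = nx.Graph()
        for i in range(12):
            for j in range(i + 1, 12):
                G.add_edge(i, j, weight=w.weights[i, j])
        ref = nx.maximum_spanning_tree(G)
        got = sum(w.weights[u, v] for u, v in t.links)
        assert got == pytest.approx(ref.size(weight="weight"))

    def test_tree_properties(self):
        for seed in range(4):
            w = random_connectome(15, seed + 20)
            t = mst_filter(w)
            assert t.m == 14
            assert local_efficiency(t) == 0.0  # no triangles in a tree
            assert not list(nx.cycle_basis(t.to_networkx()))
            assert t.m * 2 / t.n <= 2.0  # mean degree k <= 2

    def test_two_nodes(self):
        w = WeightedConnectome([[0, 0.7], [0.7, 0]])
        assert mst_filter(w).m == 1

    def test_forest_on_disconnected_support(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 0.5
        assert mst_filter(WeightedConnectome(m)).m == 2


class TestPmfgFilter:
    def test_k4_is_planar_keeps_all(self):
        w = random_connectome(4, 11)
        assert pmfg_filter(w).m == 6

    def test_k5_drops_exactly_one(self):
        w = random_connectome(5, 12)
        g = pmfg_filter(w)
        assert g.m == 9
        planar, _ = nx.check_planarity(g.to_networkx())
        assert planar

    @pytest.mark.parametrize("seed", range(3))
    def test_complete_matrix_reaches_maximal_planar_bound(self, seed):
        n = 10
        w = random_connectome(n, 30 + seed)
        g = pmfg_filter(w)
        assert g.m == 3 * (n - 2)
        planar, _ = nx.check_planarity(g.to_networkx())
        assert planar

    def test_contains_spanning_tree(self):
        w = random_connectome(9, 40)
        assert mst_filter(w).links <= pmfg_filter(w).links

    def test_rejects_directed(self):
        r = np.random.default_rng(0)
        w = WeightedConnectome(r.random((5, 5)), directed=True)
        with pytest.raises(ValueError):
            pmfg_filter(w)


class TestMstEcoFilter:
    def test_link_count_and_superset(self):
        w = random_connectome(10, 50)
        g = mst_eco_filter(w)
        assert g.m == 15  # 9 tree links + 6 strongest extras
        assert mst_filter(w).links <= g.links

    def test_connected_when_tree_spans(self):
        w = random_connectome(20, 51)
        assert nx.is_connected(mst_eco_filter(w).to_networkx())

    def test_boundary_small_n_is_complete(self):
        w = random_connectome(4, 52)
        assert mst_eco_filter(w).m == 6

    def test_identical_to_eco_when_tree_is_strongest(self):
        # weights so that the heaviest 3n/2 links contain a spanning path
        n = 8
        m = np.zeros((n, n))
        val = 100.0
        for i in range(n - 1):  # spanning path gets the top weights
            m[i, i + 1] = m[i + 1, i] = val
            val -= 1
        r = np.random.default_rng(0)
        for i in range(n):
            for j in range(i + 2, n):
                m[i, j] = m[j, i] = r.random()
        w = WeightedConnectome(m)
        assert mst_eco_filter(w) == eco_filter(w)
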