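"""Graph container and metric tests, cross-checked against networkx."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from econet import (
    BinaryGraph,
    betweenness_vector,
    degree_vector,
    density,
    global_efficiency,
    largest_component_fraction,
    local_efficiency,
    shortest_path_lengths,
)

from conftest import complete_graph, matching_graph, random_graph


# a compact hypothesis strategy for small graphs: n plus an edge bitmask
@st.composite
def small_graphs(draw, max_n=8, directed=False):
    n = draw(st.integers(2, max_n))
    pairs = (
        [(i, j) for i in range(n) for j in range(n) if i != j]
        if directed
        else [(i, j) for i in range(n) for j in range(i + 1, n)]
    )
    mask = draw(st.lists(st.booleans(), min_size=len(pairs), max_size=len(pairs)))
    return BinaryGraph(n, [p for p, keep in zip(pairs, mask) if keep], directed=directed)


class TestContainer:
    def test_rejects_self_loops_and_out_of_range(self):
        with pytest.raises(ValueError):
            BinaryGraph(3, [(1, 1)])
        with pytest.raises(ValueError):
            BinaryGraph(3, [(0, 3)])
        with pytest.raises(ValueError):
            BinaryGraph(0)

    def test_undirected_links_canonical_and_deduplicated(self):
        g = BinaryGraph(3, [(2, 0), (0, 2), (1, 0)])
        assert g.links == frozenset({(0, 2), (0, 1)})

    def test_directed_keeps_arc_orientation(self):
        g = BinaryGraph(3, [(2, 0), (0, 2)], directed=True)
        assert g.m == 2

    def test_networkx_round_trip(self, rng):
        g = random_graph(7, 0.4, rng)
        assert BinaryGraph.from_networkx(g.to_networkx()) == g


class TestDensity:
    @pytest.mark.parametrize(
        "g,expected",
        [
            (complete_graph(4), 1.0),
            (BinaryGraph(10), 0.0),
            (BinaryGraph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]), 0.5),
        ],
    )
    def test_examples(self, g, expected):
        assert density(g) == expected

    def test_single_node_is_invalid(self):
        with pytest.raises(ValueError):
            density(BinaryGraph(1))

    def test_directed_normalizes_by_ordered_pairs(self):
        g = BinaryGraph(3, [(0, 1), (1, 2), (2, 0)], directed=True)
        assert density(g) == pytest.approx(0.5)


class TestShortestPaths:
    def test_path_graph(self, path3):
        d = shortest_path_lengths(path3)
        assert d[0, 2] == 2 and d[0, 1] == 1 and d[0, 0] == 0

    def test_disconnected_pairs_marked_infinite(self):
        g = BinaryGraph(4, [(0, 1), (2, 3)])
        d = shortest_path_lengths(g)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3]) and d[0, 1] == 1

    def test_directed_cycle_asymmetry(self):
        g = BinaryGraph(3, [(0, 1), (1, 2), (2, 0)], directed=True)
        d = shortest_path_lengths(g)
        assert d[2, 1] == 2 and d[1, 2] == 1


class TestGlobalEfficiency:
    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_complete_graph_is_one(self, n):
        assert global_efficiency(complete_graph(n)) == 1.0

    def test_path3(self, path3):
        assert global_efficiency(path3) == pytest.approx(5 / 6)

    def test_perfect_matching(self):
        assert global_efficiency(matching_graph(6)) == pytest.approx(0.2)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(BinaryGraph(5)) == 0.0

    @given(small_graphs())
    def test_matches_networkx_oracle(self, g):
        assert global_efficiency(g) == pytest.approx(
            nx.global_efficiency(g.to_networkx()), abs=1e-12
        )

    @given(small_graphs(max_n=6))
    def test_matches_brute_force_distance_enumeration(self, g):
        """Eg equals the direct sum over pairs of inverse BFS distances."""
        total = 0.0
        G = g.to_networkx()
        for i in range(g.n):
            lengths = nx.single_source_shortest_path_length(G, i)
            total += sum(1.0 / d for node, d in lengths.items() if node != i)
        assert global_efficiency(g) == pytest.approx(total / (g.n * (g.n - 1)))

    def test_bounds_and_directed_symmetrization_consistency(self, rng):
        for _ in range(10):
            g = random_graph(12, rng.random() * 0.5, rng, directed=True)
            eg = global_efficiency(g)
            assert 0.0 <= eg <= 1.0
            assert global_efficiency(g.as_undirected()) >= eg - 1e-12


class TestLocalEfficiency:
    def test_triangle_is_one(self, triangle):
        assert local_efficiency(triangle) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trees_have_zero_local_efficiency(self, seed):
        t = nx.random_labeled_tree(12, seed=seed)
        assert local_efficiency(BinaryGraph.from_networkx(t)) == 0.0

    def test_star_is_zero(self, star4):
        assert local_efficiency(star4) == 0.0

    @given(small_graphs())
    def test_matches_networkx_oracle(self, g):
        assert local_efficiency(g) == pytest.approx(
            nx.local_efficiency(g.to_networkx()), abs=1e-12
        )

    def test_dense_neighborhoods_use_same_definition(self, rng):
        # exercises the csgraph fast path (neighbourhood size >= cutoff)
        g = random_graph(40, 0.7, rng)
        assert local_efficiency(g) == pytest.approx(
            nx.local_efficiency(g.to_networkx()), abs=1e-12
        )

    def test_directed_agrees_with_symmetrized_when_reciprocal(self):
        tri = BinaryGraph(
            3, [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)], directed=True
        )
        assert local_efficiency(tri) == 1.0


class TestDegreeAndBetweenness:
    def test_star_degrees(self, star4):
        assert degree_vector(star4).values.tolist() == [3, 1, 1, 1]

    def test_empty_graph_degrees(self):
        assert degree_vector(BinaryGraph(4)).values.tolist() == [0, 0, 0, 0]

    def test_ring_lattice_regular(self):
        from econet import ring_lattice

        assert set(degree_vector(ring_lattice(8, 4)).values) == {4.0}

    def test_directed_total_degree_sums_to_2m(self, rng):
        g = random_graph(10, 0.3, rng, directed=True)
        assert degree_vector(g).values.sum() == 2 * g.m

    def test_path_betweenness(self, path3):
        assert betweenness_vector(path3).values.tolist() == [0, 1, 0]

    def test_star_hub_betweenness(self, star4):
        assert betweenness_vector(star4).values[0] == 3

    def test_complete_graph_betweenness_zero(self):
        assert betweenness_vector(complete_graph(5)).values.tolist() == [0] * 5

    @pytest.mark.parametrize("seed", [3, 4])
    def test_tree_betweenness_totals(self, seed):
        """On trees, total betweenness = sum over pairs of (path length - 1)."""
        t = nx.random_labeled_tree(10, seed=seed)
        g = BinaryGraph.from_networkx(t)
        total = betweenness_vector(g).values.sum()
        d = shortest_path_lengths(g)
        iu = np.triu_indices(g.n, 1)
        assert total == pytest.approx((d[iu] - 1).sum())


class TestLargestComponent:
    def test_connected_graph(self, triangle):
        assert largest_component_fraction(triangle) == 1.0

    def test_two_equal_components(self):
        g = BinaryGraph(10, [(i, i + 1) for i in range(4)] + [(i, i + 1) for i in range(5, 9)])
        assert largest_component_fraction(g) == 0.5

    def test_directed_uses_weak_connectivity(self):
        g = BinaryGraph(3, [(0, 1), (2, 1)], directed=True)
        assert largest_component_fraction(g) == 1.0


class TestMonotonicity:
    def test_eg_nondecreasing_under_link_addition(self, rng):
        """Adding links can only shorten paths, so Eg never decreases."""
        pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)]
        order = rng.permutation(len(pairs))
        prev = 0.0
        links = []
        for t in order[:30]:
            links.append(pairs[t])
            eg = global_efficiency(BinaryGraph(12, links))
            assert eg >= prev - 1e-12
            prev = eg

    def test_el_bounded(self, rng):
        for _ in range(10):
            g = random_graph(10, rng.random(), rng)
            assert 0.0 <= local_efficiency(g) <= 1.0
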