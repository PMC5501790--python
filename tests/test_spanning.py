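import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcscaffold.spanning import (
    SpanningForest,
    component_summary,
    degree_profiles,
    msf_greedy,
    msf_rowmax,
    mst_complete,
)

from conftest import random_correlation_like


def distinct_weight_matrix(rng, n):
    """Symmetric matrix whose off-diagonal entries are pairwise distinct."""
    m = n * (n - 1) // 2
    vals = rng.permutation(m) + rng.random(m)  # distinct by construction
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w[iu] = vals
    return w + w.T


def exhaustive_max_tree_weight(w):
    """Enumerate all spanning trees (N <= 7) and return the best total weight."""
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    edges = list(zip(iu, ju))
    best = -np.inf
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() == n and nx.is_connected(g):
            best = max(best, sum(w[i, j] for i, j in combo))
    return best


class TestMsfRowmax:
    def test_four_node_example(self, four_node_w):
        forest = msf_rowmax(four_node_w)
        assert {(s, t) for s, t, _ in forest.arcs} == {(0, 1), (1, 0), (2, 3), (3, 2)}
        assert sorted(len(c) for c in forest.components) == [2, 2]
        assert len(forest.reciprocated_pairs) == 2

    def test_two_nodes_reciprocated(self):
        forest = msf_rowmax(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert forest.reciprocated_pairs == {frozenset((0, 1))}

    def test_chain_with_decaying_weights_recovered_as_path(self):
        # weights decay along the chain, so every node points backwards and
        # the component reproduces the chain
        n = 6
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 0.9 - 0.1 * i
        forest = msf_rowmax(w + 0.001)  # background keeps the matrix fully weighted
        support = forest.undirected_support()
        assert set(map(frozenset, support.edges())) == {
            frozenset((i, i + 1)) for i in range(n - 1)
        }
        assert len(forest.components) == 1

    def test_row_tie_smallest_index(self):
        w = np.array([[0, 0.5, 0.5], [0.5, 0, 0.1], [0.5, 0.1, 0]])
        forest = msf_rowmax(w)
        assert forest.arcs[0][:2] == (0, 1)

    def test_all_equal_row_warns(self):
        w = np.full((3, 3), 0.4)
        np.fill_diagonal(w, 0)
        with pytest.warns(UserWarning, match="tie rule"):
            msf_rowmax(w)

    def test_exactly_n_arcs_and_acyclic_support(self, rng):
        w = distinct_weight_matrix(rng, 12)
        forest = msf_rowmax(w)
        assert len(forest.arcs) == 12
        support = forest.undirected_support()
        assert nx.is_forest(support)
        # reciprocated pairs account for the arc/edge difference
        assert len(forest.reciprocated_pairs) == 12 - support.number_of_edges()


class TestMsfGreedy:
    def test_four_node_example(self, four_node_w):
        g = msf_greedy(four_node_w)
        assert set(map(frozenset, g.edges())) == {frozenset((0, 1)), frozenset((2, 3))}

    def test_path_takes_all_edges(self):
        # a-b=3 > b-c=2 > c-d=1: each step still finds a degree-zero endpoint
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3
        w[1, 2] = w[2, 1] = 2
        w[2, 3] = w[3, 2] = 1
        g = msf_greedy(w)
        assert set(map(frozenset, g.edges())) == {
            frozenset((0, 1)), frozenset((1, 2)), frozenset((2, 3))
        }

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equivalent_to_rowmax_support(self, seed):
        """The two constructions in the strongest-link filter are the same
        forest whenever weights are distinct."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        w = distinct_weight_matrix(rng, n)
        rowmax_edges = set(map(frozenset, msf_rowmax(w).undirected_support().edges()))
        greedy_edges = set(map(frozenset, msf_greedy(w).edges()))
        assert rowmax_edges == greedy_edges


class TestMstComplete:
    def test_four_node_example(self, four_node_w):
        tree = mst_complete(msf_rowmax(four_node_w), four_node_w)
        assert set(map(frozenset, ((a, b) for a, b, _ in tree.edges))) == {
            frozenset((0, 1)), frozenset((2, 3)), frozenset((1, 2))
        }
        assert tree.total_weight == pytest.approx(2.1)

    def test_single_component_forest_unchanged(self):
        n = 5
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 0.9 - 0.1 * i
        w += 0.001 * (1 - np.eye(n))
        forest = msf_rowmax(w)
        assert len(forest.components) == 1
        tree = mst_complete(forest, w)
        assert set(map(frozenset, ((a, b) for a, b, _ in tree.edges))) == set(
            map(frozenset, forest.undirected_support().edges())
        )

    def test_kruskal_oracle_100_seeds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            w = distinct_weight_matrix(rng, 10)
            tree = mst_complete(msf_rowmax(w), w)
            oracle = nx.maximum_spanning_tree(nx.from_numpy_array(w))
            assert tree.total_weight == pytest.approx(
                oracle.size(weight="weight"), abs=1e-12 * tree.total_weight
            )

    def test_exhaustive_enumeration_small_n(self):
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(4, 7))
            w = distinct_weight_matrix(rng, n)
            tree = mst_complete(msf_rowmax(w), w)
            assert tree.total_weight == pytest.approx(exhaustive_max_tree_weight(w))

    def test_disconnected_support_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.9
        w[2, 3] = w[3, 2] = 0.8
        with pytest.raises(ValueError, match="disconnected"):
            mst_complete(msf_rowmax(w), w)


class TestDegreeProfiles:
    def test_reciprocated_pair_in_degrees(self):
        forest = msf_rowmax(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert degree_profiles(forest).counts == {1: 2}

    def test_star_hub_in_degree(self):
        # leaves all point to hub 0; hub points to its strongest leaf
        n = 5
        w = np.full((n, n), 0.01)
        w[0, 1:] = w[1:, 0] = [0.9, 0.8, 0.7, 0.6]
        np.fill_diagonal(w, 0)
        prof = degree_profiles(msf_rowmax(w))
        assert prof.max_degree == 4
        assert prof.counts[0] == 3  # leaves 2..4 receive nothing

    def test_chain_score_path_vs_star(self):
        path = nx.path_graph(6)
        star = nx.star_graph(4)  # 5 nodes
        assert degree_profiles(path).chain_score == 1.0
        assert degree_profiles(star).chain_score == pytest.approx(4 / 5)

    def test_fractions_sum_to_one(self, rng):
        w = distinct_weight_matrix(rng, 9)
        prof = degree_profiles(msf_rowmax(w))
        assert sum(prof.fractions.values()) == pytest.approx(1.0)


class TestComponentSummary:
    def test_four_node_example_two_rows(self, four_node_w):
        table = component_summary(msf_rowmax(four_node_w))
        assert list(table["size"]) == [2, 2]
        assert table["reciprocated"].all()

    def test_chain_component_score_one(self):
        n = 5
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 0.9 - 0.1 * i
        w += 0.001 * (1 - np.eye(n))
        table = component_summary(msf_rowmax(w))
        assert len(table) == 1
        assert table.loc[0, "chain_score"] == 1.0

    def test_groups_empty_without_label_file(self, four_node_w):
        table = component_summary(msf_rowmax(four_node_w), roi_groups=None)
        assert (table["groups"] == "").all()

    def test_groups_joined_when_provided(self, four_node_w):
        labels = ["a", "b", "c", "d"]
        table = component_summary(
            msf_rowmax(four_node_w), roi_labels=labels,
            roi_groups={"a": "Frontal", "b": "Frontal", "c": "Occipital"},
        )
        assert set(table["groups"]) == {"Frontal", "Occipital"}
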