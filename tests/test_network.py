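import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foundertrace as ft
from foundertrace.network import encode_binary

from conftest import steiner_minimum


def assert_single_step_edges(net):
    """Every edge changes exactly one character by exactly one step."""
    for u, v in net.graph.edges:
        diff = net.states[u] - net.states[v]
        nz = np.flatnonzero(diff)
        assert len(nz) == 1
        assert abs(int(diff[nz[0]])) == 1


class TestMedianJoining:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ft.median_joining_network([])

    def test_identical_profiles_collapse_to_one_node(self, profile):
        reps = {"L0": 14, "L1": 10}
        net = ft.median_joining_network(
            [profile("a", reps), profile("b", reps, role="sink")])
        assert net.graph.number_of_nodes() == 1
        (node,) = net.graph.nodes
        assert net.graph.nodes[node]["count"] == 2

    def test_single_repeat_difference_gives_labelled_edge(self, profile):
        net = ft.median_joining_network(
            [profile("a", {"L0": 14, "L1": 10}),
             profile("b", {"L0": 15, "L1": 10})])
        assert net.graph.number_of_nodes() == 2
        ((u, v, d),) = net.graph.edges(data=True)
        assert d["character"] == "L0"

    def test_median_triple_adds_steiner_node(self, hap):
        a, b, c = (16100, "A"), (16200, "C"), (16300, "T")
        net = ft.median_joining_network(
            [hap("1", {a, b}), hap("2", {a, c}), hap("3", {b, c})])
        kinds = [d["kind"] for _, d in net.graph.nodes(data=True)]
        assert kinds.count("median") == 1
        assert net.total_cost() == 3.0
        assert_single_step_edges(net)

    def test_multi_step_links_expand_through_intermediates(self, profile):
        net = ft.median_joining_network(
            [profile("a", {"L0": 12}), profile("b", {"L0": 15})])
        # 3-step difference -> 2 inferred intermediates, 3 unit edges
        assert net.graph.number_of_nodes() == 4
        assert net.graph.number_of_edges() == 3
        assert_single_step_edges(net)

    @pytest.mark.parametrize("seed", range(8))
    def test_cost_never_exceeds_observed_mst(self, seed, hap):
        rng = np.random.default_rng(seed)
        n, c = int(rng.integers(3, 8)), int(rng.integers(3, 7))
        X = rng.integers(0, 2, size=(n, c))
        haps = [hap(f"s{i}", {(16051 + j, "A") for j in range(c)
                              if X[i, j]}) for i in range(n)]
        net = ft.median_joining_network(haps)
        from scipy.sparse.csgraph import minimum_spanning_tree
        from foundertrace.network import _distance_matrix

        _, Xe = encode_binary(haps)
        Xu = np.unique(Xe, axis=0)
        obs_mst = float(minimum_spanning_tree(
            _distance_matrix(Xu, np.ones(Xe.shape[1]))).sum())
        assert net.total_cost() <= obs_mst + 1e-9
        assert_single_step_edges(net)

    def test_deterministic_given_input(self, profile):
        profs = [profile(f"p{i}", {"L0": 12 + i % 3, "L1": 10 + i // 3})
                 for i in range(6)]
        n1 = ft.median_joining_network(profs)
        n2 = ft.median_joining_network(profs)
        assert sorted(n1.graph.nodes) == sorted(n2.graph.nodes)
        assert sorted(map(sorted, n1.graph.edges)) \
            == sorted(map(sorted, n2.graph.edges))


@st.composite
def str_profile_sets(draw):
    n_loci = draw(st.integers(2, 4))
    n = draw(st.integers(1, 6))
    rows = draw(st.lists(
        st.tuples(*[st.integers(8, 14) for _ in range(n_loci)]),
        min_size=n, max_size=n))
    return [ft.STRProfile(f"p{i}", "P", "source",
                          {f"L{j}": r[j] for j in range(n_loci)})
            for i, r in enumerate(rows)]


class TestStructuralInvariants:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(str_profile_sets())
    def test_every_edge_is_a_single_step(self, profiles):
        net = ft.median_joining_network(profiles)
        assert_single_step_edges(net)
        # every observed haplotype is present as a node
        for p in profiles:
            label = "-".join(str(p.repeats[l]) for l in sorted(p.repeats))
            assert label in net.graph

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(str_profile_sets())
    def test_network_connected_and_counts_conserved(self, profiles):
        import networkx as nx

        net = ft.median_joining_network(profiles)
        assert nx.is_connected(net.graph)
        total = sum(d["count"] for _, d in net.graph.nodes(data=True))
        assert total == len(profiles)


class TestSteinerOracle:
    """Network length equals the brute-force weighted Steiner minimum on
    small inputs (exhaustive median enumeration oracle)."""

    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_binary_sets(self, seed, hap):
        rng = np.random.default_rng(seed)
        n, c = int(rng.integers(3, 7)), int(rng.integers(3, 6))
        X = rng.integers(0, 2, size=(n, c))
        X = X[:, X.any(axis=0)]
        if X.shape[1] == 0:
            return
        haps = [hap(f"s{i}", {(16051 + j, "A") for j in range(X.shape[1])
                              if X[i, j]}) for i in range(n)]
        net = ft.median_joining_network(haps)
        oracle = steiner_minimum(X, np.ones(X.shape[1]), max_added=2)
        assert net.total_cost() == pytest.approx(oracle)

    def test_known_hard_case_with_two_steiner_points(self, hap):
        # needs two added medians to reach the optimum of 6
        rows = [(1, 1, 0, 0), (0, 0, 0, 0), (0, 1, 1, 0), (1, 1, 1, 1),
                (1, 0, 0, 1)]
        haps = [hap(f"s{i}", {(16051 + j, "A") for j in range(4) if r[j]})
                for i, r in enumerate(rows)]
        net = ft.median_joining_network(haps)
        assert net.total_cost() == pytest.approx(6.0)

    def test_str_triple(self, profile):
        profs = [profile("a", {"L0": 14, "L1": 10, "L2": 8}),
                 profile("b", {"L0": 15, "L1": 11, "L2": 8}),
                 profile("c", {"L0": 15, "L1": 10, "L2": 9})]
        net = ft.median_joining_network(profs)
        X = np.array([[14, 10, 8], [15, 11, 8], [15, 10, 9]])
        # STR characters carry the flat default weight of 10
        oracle = steiner_minimum(X, np.full(3, 10.0), max_added=2)
        assert net.total_cost() == pytest.approx(oracle)


class TestReducedMedian:
    def test_conflict_free_data_give_perfect_phylogeny(self, hap):
        haps = [hap("0", set()), hap("1", {(16100, "A")}),
                hap("2", {(16100, "A"), (16150, "C")}),
                hap("3", {(16200, "T")})]
        net = ft.reduced_median_network(haps)
        import networkx as nx

        assert nx.is_tree(net.graph)
        assert net.graph.number_of_edges() == 3  # one per character

    def test_weighted_reticulation_resolved_by_fast_character(self, hap):
        a, b = (16100, "A"), (16200, "T")
        haps = [hap("0", set()), hap("1", {a}), hap("2", {b}),
                hap("3", {a, b})]
        net = ft.reduced_median_network(
            haps, weights={"16100A": 1, "16200T": 10})
        import networkx as nx

        assert nx.is_tree(net.graph)
        chars = [d["character"] for _, _, d in net.graph.edges(data=True)]
        assert chars.count("16100A") == 2  # the fast character recurs
        assert chars.count("16200T") == 1

    def test_equal_weight_reticulation_retained(self, hap):
        a, b = (16100, "A"), (16200, "T")
        haps = [hap("0", set()), hap("1", {a}), hap("2", {b}),
                hap("3", {a, b})]
        net = ft.reduced_median_network(haps)
        assert net.graph.number_of_edges() == 4

    def test_single_haplotype_single_node(self, hap):
        net = ft.reduced_median_network([hap("0", {(16100, "A")})])
        assert net.graph.number_of_nodes() == 1

    def test_multistate_input_rejected(self, profile):
        with pytest.raises(ValueError, match="binary"):
            ft.reduced_median_network(
                [profile("a", {"L0": 12}), profile("b", {"L0": 15})])


class TestIterateWeights:
    def test_occurrence_counts_map_reversed_onto_1_10(self):
        from foundertrace.network import _counts_to_weights

        assert _counts_to_weights({"A": 9, "B": 1}) == {"A": 1.0, "B": 10.0}
        assert _counts_to_weights({"A": 5, "B": 5}) == {"A": 10.0, "B": 10.0}

    def test_equal_occurrences_keep_flat_weights(self, profile):
        profs = [profile("a", {"L0": 12, "L1": 10}),
                 profile("b", {"L0": 13, "L1": 11})]
        scheme, net = ft.iterate_str_weights(profs)
        assert set(scheme.weights.values()) == {10.0}
        assert scheme.converged
        assert scheme.iteration_count == 1

    def test_dominant_locus_downweighted_and_stable(self, profile):
        # L0 mutates on every inter-node link, others never
        profs = [profile(f"p{i}", {"L0": 10 + i, "L1": 14, "L2": 9})
                 for i in range(5)]
        scheme, net = ft.iterate_str_weights(profs)
        assert scheme.weights["L0"] == 1.0
        assert scheme.weights["L1"] == 10.0
        assert scheme.weights["L2"] == 10.0
        assert scheme.converged
        assert scheme.iteration_count <= 2

    def test_needs_two_distinct_profiles(self, profile):
        reps = {"L0": 12}
        with pytest.raises(ValueError, match="distinct"):
            ft.iterate_str_weights([profile("a", reps), profile("b", reps)])


class TestRooting:
    def test_midpoint_of_three_node_path(self, hap):
        haps = [hap("a", set()), hap("b", {(16100, "A")}),
                hap("c", {(16100, "A"), (16150, "C")})]
        tree = ft.root_network(ft.median_joining_network(haps), "midpoint")
        assert tree.root == "16100A"

    def test_midpoint_of_star_is_hub(self, hap):
        haps = [hap("hub", set())] + [
            hap(f"l{i}", {(16100 + 10 * i, "A")}) for i in range(5)]
        tree = ft.root_network(ft.median_joining_network(haps), "midpoint")
        assert tree.root == "ref"

    def test_outgroup_equal_to_observed_node_roots_there(self, hap):
        haps = [hap("a", set()), hap("b", {(16100, "A")}),
                hap("c", {(16100, "A"), (16150, "C")})]
        net = ft.median_joining_network(haps)
        tree = ft.root_network(net, "outgroup_consensus",
                               outgroup=haps[2])
        assert tree.root == "16100A 16150C"

    def test_missing_outgroup_is_an_error(self, hap):
        net = ft.median_joining_network([hap("a", set()),
                                         hap("b", {(16100, "A")})])
        with pytest.raises(ValueError, match="outgroup"):
            ft.root_network(net, "outgroup_consensus")

    def test_rooted_tree_depths_count_steps(self, profile):
        net = ft.median_joining_network(
            [profile("a", {"L0": 12}), profile("b", {"L0": 15})])
        tree = ft.root_network(net, "outgroup_consensus",
                               outgroup=ft.STRProfile("og", "P", "excluded",
                                                      {"L0": 12}))
        assert tree.root == "12"
        assert tree.depth_steps("15") == 3
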