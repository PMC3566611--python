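"""Network construction, X–Y subnetworks and summary statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sexnet import InteractionNetwork, merge_networks, restrict_nodes
from sexnet.network import (ANY_CLASS, read_edge_list, subnetwork,
                            subnetwork_degrees, summarize_subnetwork,
                            write_edge_list)


class TestEdgeListIO:
    def test_dedup_reversal_and_self_loops(self, tmp_path):
        p = tmp_path / "edges.txt"
        p.write_text("a b\nb a\na b\nc c\n")
        net = read_edge_list(p)
        assert net.nodes == {"a", "b"}
        assert net.edges == {frozenset(("a", "b"))}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        net = read_edge_list(p)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_path_of_two_edges(self, tmp_path):
        p = tmp_path / "edges.txt"
        p.write_text("a b\nb c\n")
        net = read_edge_list(p)
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("a b\na b c\n")
        with pytest.raises(ValueError, match="line 2"):
            read_edge_list(p)

    def test_round_trip(self, tmp_path, toy_network):
        p = tmp_path / "out.txt"
        write_edge_list(toy_network, p)
        assert read_edge_list(p) == toy_network


class TestMergeRestrict:
    def test_union_deduplicates(self):
        a = InteractionNetwork([("a", "b")])
        b = InteractionNetwork([("a", "b"), ("b", "c")])
        merged = merge_networks([a, b])
        assert merged.edges == {frozenset("ab"), frozenset("bc")}

    def test_single_network_identity(self, toy_network):
        assert merge_networks([toy_network]) == toy_network

    def test_disjoint_networks_sum(self):
        nets = [InteractionNetwork([(f"a{i}", f"b{i}")]) for i in range(4)]
        assert merge_networks(nets).n_edges == 4

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            merge_networks([])

    def test_restrict_drops_cut_edges_and_isolates(self):
        path = InteractionNetwork([("a", "b"), ("b", "c")])
        out = restrict_nodes(path, {"a", "b"})
        assert out.nodes == {"a", "b"}
        assert out.edges == {frozenset("ab")}
        # "c" removed cuts b-c; a lone retained node with no edge vanishes
        assert restrict_nodes(path, {"a", "c"}).n_nodes == 0

    def test_restrict_identity_and_idempotence(self, toy_network):
        full = restrict_nodes(toy_network, toy_network.nodes)
        assert full == toy_network
        once = restrict_nodes(toy_network, {"u1", "m1", "f1"})
        assert restrict_nodes(once, {"u1", "m1", "f1"}) == once

    def test_restrict_to_empty(self, toy_network):
        assert restrict_nodes(toy_network, set()).n_nodes == 0


class TestSubnetwork:
    def test_toy_graph_enumeration(self, toy_network, toy_labels):
        nodes, edges = subnetwork(toy_network, toy_labels, "M", "M")
        assert nodes == {"m1", "m2"}
        assert edges == {frozenset(("m1", "m2"))}
        nodes, edges = subnetwork(toy_network, toy_labels, "M", "F")
        assert nodes == {"m1"}
        assert edges == {frozenset(("m1", "f1"))}
        nodes, edges = subnetwork(toy_network, toy_labels, "U", ANY_CLASS)
        assert nodes == {"u1"}
        assert edges == {frozenset(("u1", "m1")), frozenset(("u1", "f1"))}

    def test_edge_count_symmetry(self, toy_network, toy_labels):
        for x in "UFM":
            for y in "UFM":
                _, e_xy = subnetwork(toy_network, toy_labels, x, y)
                _, e_yx = subnetwork(toy_network, toy_labels, y, x)
                assert e_xy == e_yx

    def test_absent_class_gives_empty(self, toy_network):
        labels = {n: "U" for n in toy_network.nodes}
        nodes, edges = subnetwork(toy_network, labels, "M", "M")
        assert nodes == set() and edges == set()

    def test_unlabeled_node_rejected(self, toy_network):
        with pytest.raises(ValueError, match="u1"):
            subnetwork(toy_network, {"m1": "M", "m2": "M", "f1": "F"},
                       "M", "M")


class TestSummaries:
    def test_triangle_all_all(self):
        tri = InteractionNetwork([("a", "b"), ("b", "c"), ("c", "a")])
        labels = {n: "U" for n in tri.nodes}
        s = summarize_subnetwork(tri, labels, ANY_CLASS, ANY_CLASS)
        assert (s.n_nodes, s.n_edges) == (3, 3)
        assert s.edges_per_node == pytest.approx(1.0)
        assert s.mean_degree == pytest.approx(2.0)
        assert s.sd_degree == pytest.approx(0.0)

    def test_degree_modes_differ(self, toy_network, toy_labels):
        within = summarize_subnetwork(toy_network, toy_labels, "M", "M",
                                      degree_mode="within")
        full = summarize_subnetwork(toy_network, toy_labels, "M", "M",
                                    degree_mode="full")
        assert within.mean_degree == pytest.approx(1.0)
        assert full.mean_degree == pytest.approx(2.0)  # deg(m1)=3, deg(m2)=1

    def test_empty_subnetwork_flagged(self, toy_network):
        labels = {n: "U" for n in toy_network.nodes}
        s = summarize_subnetwork(toy_network, labels, "M", "M")
        assert s.n_nodes == 0 and math.isnan(s.edges_per_node)

    def test_within_degrees_are_positive(self, toy_network, toy_labels):
        for x in ("U", "F", "M", ANY_CLASS):
            degs = subnetwork_degrees(toy_network, toy_labels, x, ANY_CLASS,
                                      degree_mode="within")
            assert all(d >= 1 for d in degs)


def _random_labeled_graph(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    nodes = [f"n{i}" for i in range(n)]
    edges = [(nodes[i], nodes[j])
             for i in range(n) for j in range(i + 1, n)
             if rng.random() < 0.2]
    net = InteractionNetwork(edges, nodes=nodes)
    labels = {v: "UFM"[rng.integers(3)] for v in nodes}
    return net, labels


@given(seed=st.integers(0, 200))
@settings(max_examples=30, deadline=None)
def test_edge_partition_identity(seed):
    """Unordered class-pair edge sets partition the full edge set."""
    net, labels = _random_labeled_graph(seed)
    total = 0
    for x, y in ("UU", "UF", "UM", "FF", "FM", "MM"):
        _, e = subnetwork(net, labels, x, y)
        total += len(e)
    _, e_all = subnetwork(net, labels, ANY_CLASS, ANY_CLASS)
    assert total == len(e_all)


@given(seed=st.integers(0, 200))
@settings(max_examples=30, deadline=None)
def test_class_node_counts_partition_non_isolated_nodes(seed):
    net, labels = _random_labeled_graph(seed)
    counted = sum(
        len(subnetwork(net, labels, x, ANY_CLASS)[0]) for x in "UFM")
    non_isolated = sum(1 for v in net.graph.nodes if net.degree(v) > 0)
    assert counted == non_isolated


@given(seed=st.integers(0, 200))
@settings(max_examples=20, deadline=None)
def test_handshake_identity_full_degree(seed):
    """For A-A, mean full degree is exactly 2·E/N."""
    net, labels = _random_labeled_graph(seed)
    s = summarize_subnetwork(net, labels, ANY_CLASS, ANY_CLASS,
                             degree_mode="full")
    if s.n_nodes:
        assert s.mean_degree == pytest.approx(2 * s.n_edges / s.n_nodes)
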