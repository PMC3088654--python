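"""Edge-betweenness decomposition, dendrograms, partition selection."""

import math

import networkx as nx
import numpy as np
import pytest

from oracles import betweenness_oracle, random_graph_suite
from psnet import (
    ThresholdNetwork,
    build_network,
    choose_partition,
    delta_removal_profile,
    edge_betweenness,
    gn_decompose,
    modularity_Q,
    partition_at,
)
from psnet.communities import UNASSIGNED, Partition


def star4():
    return ThresholdNetwork.from_edges(
        ["c", "l1", "l2", "l3"], [("c", "l1"), ("c", "l2"), ("c", "l3")]
    )


def two_triangles_bridge():
    edges = [("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
             ("b1", "b2"), ("b1", "b3"), ("b2", "b3"), ("a1", "b1")]
    return ThresholdNetwork.from_edges(
        ["a1", "a2", "a3", "b1", "b2", "b3"], edges
    )


class TestEdgeBetweenness:
    def test_single_edge(self):
        net = ThresholdNetwork.from_edges(["a", "b"], [("a", "b")])
        assert edge_betweenness(net) == {("a", "b"): 1.0}

    def test_star_edges_carry_half(self):
        b = edge_betweenness(star4())
        # each spoke carries 3 of the 6 pair geodesics
        assert all(v == pytest.approx(0.5) for v in b.values())

    def test_bridge_of_triangles_is_maximal(self):
        b = edge_betweenness(two_triangles_bridge())
        assert b[("a1", "b1")] == pytest.approx(0.6)  # 9 pairs / 15
        assert b[("a1", "b1")] == max(b.values())

    def test_matches_enumeration_oracle_on_random_suite(self):
        for g in random_graph_suite(40, max_n=8, seed=17):
            if g.number_of_edges() == 0:
                continue
            ours = edge_betweenness(ThresholdNetwork(g))
            brute = betweenness_oracle(g)
            assert set(ours) == set(brute)
            for e in ours:
                assert ours[e] == pytest.approx(brute[e], abs=1e-12)

    def test_total_betweenness_matches_geodesic_mass(self):
        # sum over edges of b equals sum over connected pairs of mean
        # geodesic length, normalized by N(N-1)/2 — checked via the oracle
        from oracles import bfs_distances

        for g in random_graph_suite(15, max_n=7, seed=23):
            if g.number_of_edges() == 0:
                continue
            n = g.number_of_nodes()
            total = sum(edge_betweenness(ThresholdNetwork(g)).values())
            mass = 0.0
            for s in g.nodes():
                d = bfs_distances(g, s)
                mass += sum(v for k, v in d.items() if k != s)
            mass /= 2  # unordered pairs
            assert total == pytest.approx(mass / (n * (n - 1) / 2))


class TestDecomposition:
    def test_bridge_removed_first_and_split_recorded(self, two_cliques_bridge):
        dend = gn_decompose(two_cliques_bridge)
        assert dend.removal_trace[0] == ("a0", "b0")
        ev = dend.split_events[0]
        assert ev.step == 1
        assert {frozenset(ev.side_a), frozenset(ev.side_b)} == {
            frozenset(f"a{i}" for i in range(4)),
            frozenset(f"b{i}" for i in range(4)),
        }

    def test_terminal_partition_is_singletons(self):
        for g in random_graph_suite(8, max_n=7, seed=31):
            net = ThresholdNetwork(g)
            dend = gn_decompose(net)
            p = partition_at(dend, dend.n_removals)
            assert all(len(s) == 1 for s in p.as_sets())

    def test_edgeless_graph_gives_empty_trace(self):
        net = ThresholdNetwork.from_edges(["a", "b", "c"], [])
        dend = gn_decompose(net)
        assert dend.removal_trace == []
        assert dend.newick() == "(a,b,c);"

    def test_deterministic_trace(self):
        for g in random_graph_suite(6, max_n=8, seed=37):
            net = ThresholdNetwork(g)
            assert gn_decompose(net).removal_trace == gn_decompose(net).removal_trace

    def test_component_count_nondecreasing_in_r(self):
        g = random_graph_suite(1, max_n=8, seed=41)[0]
        dend = gn_decompose(ThresholdNetwork(g))
        counts = [len(dend.components_at(r)) for r in range(dend.n_removals + 1)]
        assert counts == sorted(counts)


class TestRemovalProfile:
    def test_bridge_step_has_dominant_delta(self, two_cliques_bridge):
        dend = gn_decompose(two_cliques_bridge)
        prof = delta_removal_profile(dend, two_cliques_bridge)
        assert int(np.argmax(prof.deltas)) == 0  # the bridge removal
        assert prof.deltas[0] > 3 * np.median(prof.deltas[1:])

    def test_split_steps_have_positive_delta(self):
        # disconnecting a pair always changes the neighborhood structure
        for g in random_graph_suite(10, max_n=8, seed=43):
            net = ThresholdNetwork(g)
            if net.n_edges == 0:
                continue
            dend = gn_decompose(net)
            prof = delta_removal_profile(dend, net)
            for ev in dend.split_events:
                assert prof.deltas[ev.step - 1] > 0

    def test_empty_trace_rejected(self):
        net = ThresholdNetwork.from_edges(["a"], [])
        dend = gn_decompose(net)
        with pytest.raises(ValueError):
            delta_removal_profile(dend, net)


class TestModularity:
    def test_single_community_is_zero(self, two_cliques_bridge):
        p = Partition({n: 1 for n in two_cliques_bridge.labels})
        assert modularity_Q(two_cliques_bridge, p) == pytest.approx(0.0)

    def test_two_disconnected_cliques_half(self):
        edges = [("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                 ("b1", "b2"), ("b1", "b3"), ("b2", "b3")]
        net = ThresholdNetwork.from_edges(
            ["a1", "a2", "a3", "b1", "b2", "b3"], edges
        )
        p = Partition({n: 1 if n.startswith("a") else 2 for n in net.labels})
        assert modularity_Q(net, p) == pytest.approx(0.5)

    def test_random_partition_of_clique_nonpositive_and_matches_networkx(self):
        rng = np.random.default_rng(4)
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        net = ThresholdNetwork(g)
        for _ in range(5):
            labels = rng.integers(1, 4, size=6)
            p = Partition({n: int(c) for n, c in zip(net.labels, labels)})
            q = modularity_Q(net, p)
            assert q <= 1e-12
            ref = nx.algorithms.community.modularity(
                g, p.as_sets(), weight=None
            )
            assert q == pytest.approx(ref)

    def test_edgeless_undefined(self):
        net = ThresholdNetwork.from_edges(["a", "b"], [])
        with pytest.raises(ValueError):
            modularity_Q(net, Partition({"a": 1, "b": 1}))


class TestPartitionSelection:
    def test_r_zero_connected_graph_single_community(self, two_cliques_bridge):
        dend = gn_decompose(two_cliques_bridge)
        p = partition_at(dend, 0)
        assert len(p.as_sets()) == 1

    def test_bridge_graph_both_rules_find_cliques(self, two_cliques_bridge):
        dend = gn_decompose(two_cliques_bridge)
        expect = Partition(
            {n: (1 if n.startswith("a") else 2) for n in two_cliques_bridge.labels}
        )
        for rule in ("delta_peak", "max_modularity"):
            p = choose_partition(dend, two_cliques_bridge, rule=rule,
                                 min_community_size=1)
            assert p.equivalent(expect)

    def test_min_community_size_one_leaves_nothing_unassigned(self):
        g = random_graph_suite(1, max_n=8, seed=51)[0]
        net = ThresholdNetwork(g)
        dend = gn_decompose(net)
        p = choose_partition(dend, net, min_community_size=1)
        assert UNASSIGNED not in p.assignment.values()

    def test_small_components_labeled_unassigned(self):
        net = ThresholdNetwork.from_edges(
            ["a", "b", "c", "d", "e"], [("a", "b"), ("a", "c"), ("b", "c")]
        )
        dend = gn_decompose(net)
        p = partition_at(dend, 0, min_community_size=3)
        assert p.assignment["d"] == p.assignment["e"] == UNASSIGNED
        assert p.assignment["a"] == p.assignment["b"] == p.assignment["c"] != UNASSIGNED

    def test_sizes_sum_to_n_at_every_r(self):
        g = random_graph_suite(1, max_n=8, seed=53)[0]
        net = ThresholdNetwork(g)
        dend = gn_decompose(net)
        for r in range(dend.n_removals + 1):
            p = partition_at(dend, r)
            assert sum(p.sizes().values()) == net.n

    def test_r_out_of_range(self, two_cliques_bridge):
        dend = gn_decompose(two_cliques_bridge)
        with pytest.raises(ValueError):
            partition_at(dend, dend.n_removals + 1)


class TestLeafOrder:
    def test_cliques_stay_contiguous(self, two_cliques_bridge):
        dend = gn_decompose(two_cliques_bridge)
        order = dend.leaf_order()
        pos = {n: i for i, n in enumerate(order)}
        for clique in ("a", "b"):
            idx = sorted(pos[n] for n in order if n.startswith(clique))
            assert idx == list(range(idx[0], idx[0] + 4))

    def test_every_split_side_contiguous(self):
        g = random_graph_suite(1, max_n=8, seed=59)[0]
        dend = gn_decompose(ThresholdNetwork(g))
        order = dend.leaf_order()
        pos = {n: i for i, n in enumerate(order)}
        for ev in dend.split_events:
            for side in (ev.side_a, ev.side_b):
                idx = sorted(pos[n] for n in side)
                assert idx == list(range(idx[0], idx[0] + len(side)))

    def test_edgeless_graph_sorted_by_label(self):
        net = ThresholdNetwork.from_edges(["c", "a", "b"], [])
        assert gn_decompose(net).leaf_order() == ["a", "b", "c"]

    def test_planted_blocks_closer_within_than_between(self, planted):
        # in the reordered neighborhood matrix, within-block entries are
        # strictly smaller on average than (connected) between-block ones
        from psnet import neighborhood_matrix

        S, truth, _ = planted
        net = build_network(S, 25)  # half the between-block edges removed
        dend = gn_decompose(net)
        order = dend.leaf_order()
        nbm = neighborhood_matrix(net).permute(order)
        block = {n: truth.assignment[n] for n in order}
        within, between = [], []
        n = len(order)
        for i in range(n):
            for j in range(i + 1, n):
                d = nbm.entries[i, j]
                if d == 0:
                    continue
                same = block[order[i]] == block[order[j]]
                (within if same else between).append(d)
        assert np.mean(within) < np.mean(between)
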