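"""Degree metrics and alpha-tuned generalized closeness.

The closeness core is checked against an exhaustive simple-path enumeration
oracle, against independent implementations of its two limits (hop-count
BFS at alpha=0, Dijkstra on 1/w at alpha=1), and against its algebraic
weight-scaling identity.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import networkx as nx

from dahnet import (
    MetricConfig,
    average_closeness_by_type,
    channel_degree_centrality,
    generalized_closeness,
    in_degree,
    out_degree,
    rank_actors,
    shortest_distance_alpha,
)
from dahnet.typology import Actor, ActorRegistry, Category

from conftest import (
    bfs_hop_closeness,
    brute_force_closeness,
    brute_force_distances,
    random_digraph,
)


def _graph(edges):
    g = nx.DiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestMetricConfig:
    @pytest.mark.parametrize("bad", [
        {"alpha": -0.5}, {"alpha": float("nan")},
        {"direction": "sideways"}, {"unreachable_policy": "ignore"}])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            MetricConfig(**bad)


class TestDegrees:
    def test_out_degree_counts_distinct_successors(self):
        g = _graph([("A", "B", 1), ("A", "C", 1)])
        assert out_degree(g)["A"] == 2
        assert out_degree(g)["B"] == 0

    def test_isolated_node_zero(self):
        g = nx.DiGraph()
        g.add_node("X")
        assert out_degree(g)["X"] == 0 and in_degree(g)["X"] == 0

    def test_weight_invariance(self):
        light = _graph([("A", "B", 1), ("C", "B", 1)])
        heavy = _graph([("A", "B", 100), ("C", "B", 1e9)])
        assert out_degree(light) == out_degree(heavy)
        assert in_degree(light)["B"] == 2

    def test_self_loops_excluded(self):
        g = _graph([("A", "A", 5), ("A", "B", 1)])
        assert out_degree(g)["A"] == 1
        assert in_degree(g)["A"] == 0

    def test_handshake_identity_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            g = random_digraph(rng, n_max=10)
            n_edges = g.number_of_edges()
            assert sum(out_degree(g).values()) == n_edges
            assert sum(in_degree(g).values()) == n_edges


class TestChannelDegree:
    def test_sources_plus_recipients(self):
        sc = _graph([("S1", "B", 1), ("S2", "B", 1)])
        cr = _graph([("B", "R1", 1), ("B", "R2", 1), ("B", "R3", 1)])
        assert channel_degree_centrality(sc, cr)["B"] == 5

    def test_channel_with_sources_only_equals_in_degree(self):
        sc = _graph([("S1", "B", 1), ("S2", "B", 1)])
        assert channel_degree_centrality(sc, nx.DiGraph())["B"] == in_degree(sc)["B"]

    def test_equals_degree_in_merged_tripartite_graph(self, small_config):
        from dahnet import build_bipartite, drop_unspecified, generate
        flows = drop_unspecified(generate(small_config))
        year = small_config.years[-1]
        sc = build_bipartite(flows, year, "source_channel")
        cr = build_bipartite(flows, year, "channel_recipient")
        # true tripartite merge keeps the modes distinct, so an actor's
        # source-role edges never leak into its channel degree
        merged = nx.DiGraph()
        merged.add_edges_from((f"S:{u}", f"C:{v}") for u, v in sc.edges)
        merged.add_edges_from((f"C:{u}", f"R:{v}") for u, v in cr.edges)
        result = channel_degree_centrality(sc, cr)
        channels = set(flows.loc[flows["year"] == year, "channel_id"])
        for c in channels:
            # an actor channeling its own sourced funds is a self-loop in
            # role-merged terms and is excluded from the metric
            self_flow = 1 if sc.has_edge(c, c) else 0
            assert result[c] == merged.degree(f"C:{c}") - self_flow


class TestShortestDistanceAlpha:
    def test_hand_computed_two_hop(self):
        g = _graph([("A", "B", 4), ("B", "C", 4)])
        d = shortest_distance_alpha(g, "A", MetricConfig(alpha=0.5))
        assert d["C"] == pytest.approx(1.0)
        assert d["A"] == 0.0

    def test_alpha_zero_is_hop_count(self):
        g = _graph([("A", "B", 4), ("B", "C", 4)])
        d = shortest_distance_alpha(g, "A", MetricConfig(alpha=0.0))
        assert d["C"] == pytest.approx(2.0)

    def test_heavy_indirect_path_beats_light_direct_edge(self):
        g = _graph([("A", "C", 1), ("A", "B", 9), ("B", "C", 9)])
        d = shortest_distance_alpha(g, "A", MetricConfig(alpha=0.5))
        assert d["C"] == pytest.approx(2.0 / 3.0)

    def test_unreachable_absent(self):
        g = _graph([("A", "B", 1)])
        g.add_node("C")
        assert "C" not in shortest_distance_alpha(g, "A")

    def test_nonpositive_weight_rejected(self):
        g = _graph([("A", "B", 0.0)])
        with pytest.raises(ValueError, match="non-positive"):
            shortest_distance_alpha(g, "A")

    def test_unknown_source_rejected(self):
        with pytest.raises(KeyError):
            shortest_distance_alpha(nx.DiGraph(), "ghost")

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_matches_exhaustive_enumeration(self, alpha):
        rng = np.random.default_rng(17)
        for _ in range(60):
            g = random_digraph(rng)
            cfg = MetricConfig(alpha=alpha)
            for node in g.nodes:
                got = shortest_distance_alpha(g, node, cfg)
                want = brute_force_distances(g, node, alpha)
                assert got.keys() == want.keys()
                for j in want:
                    assert got[j] == pytest.approx(want[j], abs=1e-9)


class TestGeneralizedCloseness:
    def test_path_graph_hand_values(self):
        g = _graph([("A", "B", 1), ("B", "C", 1)])
        for alpha in (0.0, 0.5, 2.0):
            cl = generalized_closeness(g, MetricConfig(alpha=alpha))
            assert cl["A"] == pytest.approx(1.0 / 3.0)
            assert cl["B"] == pytest.approx(1.0)
            assert cl["C"] == 0.0  # sink reaches nobody

    def test_single_node_graph(self):
        g = nx.DiGraph()
        g.add_node("A")
        assert generalized_closeness(g) == {"A": 0.0}

    def test_uniform_weight_scale_identity(self):
        # with all weights c, closeness = (unit-weight closeness) * c**alpha
        rng = np.random.default_rng(23)
        g = random_digraph(rng, n_max=7, p=0.5)
        c, alpha = 7.5, 0.5
        unit = g.copy()
        nx.set_edge_attributes(unit, 1.0, "weight")
        scaled = g.copy()
        nx.set_edge_attributes(scaled, c, "weight")
        base = generalized_closeness(unit, MetricConfig(alpha=alpha))
        got = generalized_closeness(scaled, MetricConfig(alpha=alpha))
        for node in g.nodes:
            assert got[node] == pytest.approx(base[node] * c**alpha, rel=1e-9)

    def test_weight_scale_covariance(self):
        # multiplying all weights by c multiplies closeness by c**alpha
        rng = np.random.default_rng(29)
        for alpha, c in [(0.5, 3.0), (1.0, 0.25), (2.0, 10.0)]:
            g = random_digraph(rng)
            scaled = g.copy()
            for u, v, d in scaled.edges(data=True):
                d["weight"] *= c
            base = generalized_closeness(g, MetricConfig(alpha=alpha))
            got = generalized_closeness(scaled, MetricConfig(alpha=alpha))
            for node in g.nodes:
                assert got[node] == pytest.approx(base[node] * c**alpha, rel=1e-9)

    def test_alpha_zero_matches_independent_bfs(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            g = random_digraph(rng)
            got = generalized_closeness(g, MetricConfig(alpha=0.0))
            want = bfs_hop_closeness(g)
            for node in g.nodes:
                assert got[node] == pytest.approx(want[node], abs=1e-12)

    def test_alpha_one_matches_dijkstra_on_inverse_costs(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            g = random_digraph(rng)
            cost = g.copy()
            for u, v, d in cost.edges(data=True):
                d["weight"] = 1.0 / d["weight"]
            got = generalized_closeness(g, MetricConfig(alpha=1.0))
            for node in g.nodes:
                lengths = nx.single_source_dijkstra_path_length(
                    cost, node, weight="weight")
                lengths.pop(node)
                want = 1.0 / sum(lengths.values()) if lengths else 0.0
                assert got[node] == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_adding_edge_never_decreases_closeness(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            g = random_digraph(rng, p=0.6)
            nodes = list(g.nodes)
            absent = [(u, v) for u in nodes for v in nodes
                      if u != v and not g.has_edge(u, v)]
            if not absent:
                continue
            u, v = absent[int(rng.integers(len(absent)))]
            before = generalized_closeness(g)
            reach_before = {n: set(nx.descendants(g, n)) for n in nodes}
            g.add_edge(u, v, weight=float(rng.uniform(0.2, 50)))
            after = generalized_closeness(g)
            for node in nodes:
                # fixed reachable set: the summation set must not have grown
                if set(nx.descendants(g, node)) == reach_before[node]:
                    assert after[node] >= before[node] - 1e-12

    def test_zero_if_any_unreachable_policy(self):
        g = _graph([("A", "B", 1), ("B", "C", 1)])
        cl = generalized_closeness(
            g, MetricConfig(unreachable_policy="zero_if_any_unreachable"))
        assert cl["A"] > 0       # A reaches everyone
        assert cl["B"] == 0.0    # B cannot reach A

    def test_direction_in_uses_incoming_distances(self):
        g = _graph([("A", "B", 1), ("B", "C", 1)])
        cl = generalized_closeness(g, MetricConfig(direction="in"))
        assert cl["C"] == pytest.approx(1.0 / 3.0)
        assert cl["A"] == 0.0

    def test_direction_undirected_symmetrizes(self):
        g = _graph([("A", "B", 2), ("B", "A", 2), ("B", "C", 4)])
        cl = generalized_closeness(g, MetricConfig(direction="undirected"))
        # reciprocal edge weights are summed: A-B carries 4
        assert cl["A"] == pytest.approx(1.0 / (0.5 + 1.0))

    def test_self_loops_ignored(self):
        plain = _graph([("A", "B", 1)])
        loopy = _graph([("A", "B", 1), ("A", "A", 1e9)])
        assert generalized_closeness(loopy) == generalized_closeness(plain)


class TestRanking:
    def test_ties_broken_lexicographically(self):
        table = rank_actors({"B": 3.0, "A": 3.0, "C": 1.0}, 2000, "closeness")
        assert table["actor_id"].tolist() == ["A", "B", "C"]
        assert table["rank"].tolist() == [1, 2, 3]

    def test_single_actor(self):
        table = rank_actors({"A": 0.5}, 1990, "out_degree")
        assert table["rank"].tolist() == [1]

    def test_ranks_are_permutation_and_non_increasing(self):
        rng = np.random.default_rng(43)
        values = {f"a{i}": float(rng.uniform()) for i in range(20)}
        table = rank_actors(values, 2000, "m")
        assert sorted(table["rank"]) == list(range(1, 21))
        assert table["value"].is_monotonic_decreasing

    @given(st.permutations(list(range(8))))
    def test_invariant_to_input_order(self, order):
        base = {f"a{i}": v for i, v in
                zip(range(8), [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])}
        shuffled = {f"a{i}": base[f"a{i}"] for i in order}
        pd.testing.assert_frame_equal(
            rank_actors(shuffled, 2000, "m"), rank_actors(base, 2000, "m"))


class TestAverageByType:
    @pytest.fixture
    def registry(self):
        r = ActorRegistry()
        r.add(Actor("cso1", category=Category.CSO, subgroup="ngo"))
        r.add(Actor("cso2", category=Category.CSO, subgroup="ngo"))
        r.add(Actor("gov", category=Category.PUBLIC,
                    subgroup="national_government"))
        return r

    def test_category_mean(self, registry):
        table = average_closeness_by_type(
            {"cso1": 0.2, "cso2": 0.4, "gov": 0.9}, registry, 2000)
        cso = table.loc[table["category"] == "CSO", "mean_closeness"].iloc[0]
        assert cso == pytest.approx(0.3)

    def test_empty_category_omitted(self, registry):
        table = average_closeness_by_type({"gov": 0.9}, registry, 2000)
        assert table["category"].tolist() == ["PUBLIC"]

    def test_grand_mean_identity(self, registry):
        # grand mean equals the size-weighted mean of category means
        values = {"cso1": 0.2, "cso2": 0.4, "gov": 0.9}
        table = average_closeness_by_type(values, registry, 2000)
        sizes = {"CSO": 2, "PUBLIC": 1}
        weighted = sum(sizes[c] * m for c, m in
                       zip(table["category"], table["mean_closeness"]))
        assert weighted / sum(sizes.values()) == pytest.approx(
            sum(values.values()) / len(values))

    def test_strict_mode_raises_on_unknown_actor(self):
        from dahnet.typology import TypologyError
        registry = ActorRegistry(policy="strict")
        with pytest.raises(TypologyError):
            average_closeness_by_type({"ghost": 0.1}, registry, 2000)
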