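"""Node metrics for directed weighted DAH networks.

Degree metrics (out-degree, in-degree, channel degree centrality) count
distinct funding relationships and ignore weights.  Closeness uses the
generalized shortest distance of Opsahl, Agneessens & Skvoretz, in which a
path's length is the sum of per-hop costs ``(1 / w)**alpha``:

    d_alpha(i, j) = min over directed paths i->j of sum_hops (1 / w_hop)**alpha
    C(i) = 1 / sum_j d_alpha(i, j)

The tuning parameter ``alpha`` trades tie count against tie intensity:
``alpha = 0`` recovers binary hop-count distance, ``alpha = 1`` classic
weighted distance on costs ``1/w``, and the default ``alpha = 0.5``
balances the two.  On a sparse directed aid network many ordered pairs are
mutually unreachable, so by default the sum runs over the targets a node
actually reaches (``reachable_only``); the literal all-targets reading,
which zeroes any node with an unreachable target, is available as
``zero_if_any_unreachable``.  Self-loops lie on no shortest path and are
excluded from every metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import networkx as nx
import pandas as pd

from .typology import ActorRegistry

__all__ = [
    "MetricConfig",
    "out_degree",
    "in_degree",
    "channel_degree_centrality",
    "shortest_distance_alpha",
    "generalized_closeness",
    "rank_actors",
    "average_closeness_by_type",
]


@dataclass(frozen=True)
class MetricConfig:
    """Closeness configuration: tuning parameter, direction, unreachable policy.

    ``direction="out"`` measures how quickly a node reaches the rest of the
    network along the flow of money; ``"in"`` uses incoming distances;
    ``"undirected"`` collapses the graph, summing reciprocal edge weights.
    """

    alpha: float = 0.5
    direction: str = "out"
    unreachable_policy: str = "reachable_only"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        if self.direction not in ("out", "in", "undirected"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.unreachable_policy not in ("reachable_only",
                                           "zero_if_any_unreachable"):
            raise ValueError(
                f"unknown unreachable_policy {self.unreachable_policy!r}")


def _metric_view(network: nx.DiGraph, config: MetricConfig) -> nx.Graph:
    """Self-loop-free view oriented per the direction convention."""
    g = network
    if nx.number_of_selfloops(g):
        g = g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
    if config.direction == "in":
        return g.reverse(copy=False)
    if config.direction == "undirected":
        u = nx.Graph()
        u.add_nodes_from(g.nodes)
        for a, b, d in g.edges(data=True):
            w = d["weight"] + (u.edges[a, b]["weight"] if u.has_edge(a, b) else 0.0)
            u.add_edge(a, b, weight=w)
        return u
    return g


def out_degree(network: nx.DiGraph) -> dict[str, int]:
    """Number of distinct actors each node funds (self-loops excluded)."""
    return {n: sum(1 for s in network.successors(n) if s != n)
            for n in network.nodes}


def in_degree(network: nx.DiGraph) -> dict[str, int]:
    """Number of distinct actors funding each node (self-loops excluded)."""
    return {n: sum(1 for p in network.predecessors(n) if p != n)
            for n in network.nodes}


def channel_degree_centrality(bipartite_sc: nx.DiGraph,
                              bipartite_cr: nx.DiGraph) -> dict[str, int]:
    """Total degree of each channel across both bipartite projections.

    For every channel this counts (distinct funding sources in the
    source->channel graph) + (distinct recipient countries funded in the
    channel->recipient graph) — the channel's degree in the merged
    tripartite graph.  Channels present in neither graph are omitted.
    """
    in_sc = in_degree(bipartite_sc)
    out_cr = out_degree(bipartite_cr)
    channels = (
        {v for _, v in bipartite_sc.edges}
        | {u for u, _ in bipartite_cr.edges}
        | {n for n, d in bipartite_sc.nodes(data=True)
           if "channel" in d.get("roles", "")}
        | {n for n, d in bipartite_cr.nodes(data=True)
           if "channel" in d.get("roles", "")}
    )
    return {c: in_sc.get(c, 0) + out_cr.get(c, 0) for c in channels}


def shortest_distance_alpha(
    network: nx.DiGraph,
    source: str,
    config: MetricConfig = MetricConfig(),
) -> dict[str, float]:
    """Generalized shortest distances from ``source`` to its reachable nodes.

    Computed by Dijkstra on the transformed costs ``(1 / weight)**alpha``
    (all positive, so shortest paths are simple).  ``d(i, i) = 0``;
    unreachable targets are absent from the mapping.
    """
    if source not in network:
        raise KeyError(f"node {source!r} not in network")
    g = _metric_view(network, config)
    alpha = config.alpha

    def cost(u, v, d):
        w = d["weight"]
        if w <= 0:
            raise ValueError(f"non-positive edge weight {w} on ({u!r}, {v!r})")
        return (1.0 / w) ** alpha

    return dict(nx.single_source_dijkstra_path_length(g, source, weight=cost))


def generalized_closeness(
    network: nx.DiGraph,
    config: MetricConfig = MetricConfig(),
) -> dict[str, float]:
    """Generalized closeness ``1 / sum_j d_alpha(i, j)`` for every node.

    Under the default ``reachable_only`` policy the sum runs over the nodes
    reachable from ``i``; a node reaching no others scores 0.  Under
    ``zero_if_any_unreachable`` any node that cannot reach every other node
    scores 0 (the literal reading of the closeness formula).  No
    normalization by network size is applied.
    """
    n_total = network.number_of_nodes()
    values: dict[str, float] = {}
    for node in network.nodes:
        dists = shortest_distance_alpha(network, node, config)
        dists.pop(node, None)
        if not dists:
            values[node] = 0.0
            continue
        if (config.unreachable_policy == "zero_if_any_unreachable"
                and len(dists) < n_total - 1):
            values[node] = 0.0
            continue
        total = sum(dists.values())
        values[node] = 1.0 / total if total > 0 else 0.0
    return values


def rank_actors(values: dict[str, float], year: int,
                metric_name: str) -> pd.DataFrame:
    """Ordinal ranking 1..k by descending value, ties broken by actor id.

    Returns long-format rows ``(year, actor_id, metric, value, rank)``;
    output is invariant to the input ordering.
    """
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(year, actor, metric_name, value, rank)
         for rank, (actor, value) in enumerate(ordered, start=1)],
        columns=["year", "actor_id", "metric", "value", "rank"],
    )


def average_closeness_by_type(
    closeness: dict[str, float],
    registry: ActorRegistry,
    year: int,
) -> pd.DataFrame:
    """Arithmetic mean closeness per actor category present in ``closeness``.

    Categories with no active actors that year produce no row.  In strict
    registry mode an unresolvable actor raises.
    """
    rows: dict[str, list[float]] = {}
    for actor, value in closeness.items():
        cat = registry.category_of(actor).value
        rows.setdefault(cat, []).append(value)
    return pd.DataFrame(
        [(year, cat, sum(vals) / len(vals)) for cat, vals in sorted(rows.items())],
        columns=["year", "category", "mean_closeness"],
    )
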