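"""Shared fixtures and independent oracles for the dahnet test suite.

The brute-force path-enumeration oracle here is deliberately written
without networkx shortest-path machinery so it stays independent of the
implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import networkx as nx

from dahnet import GeneratorConfig, default_config_mdg_era, drop_unspecified, generate, make_registry

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_distances(g: nx.DiGraph, source, alpha: float) -> dict:
    """Min over all simple directed paths of sum((1/w)**alpha) per hop.

    Exhaustive DFS enumeration; valid for small graphs only.  Self-loops
    never lie on a simple path and are skipped.
    """
    adj = {u: [(v, d["weight"]) for v, d in g[u].items() if v != u]
           for u in g.nodes}
    best: dict = {}

    def dfs(node, cost, visited):
        for nxt, w in adj[node]:
            if nxt in visited:
                continue
            c = cost + (1.0 / w) ** alpha
            if nxt not in best or c < best[nxt]:
                best[nxt] = c
            dfs(nxt, c, visited | {nxt})

    dfs(source, 0.0, {source})
    best[source] = 0.0
    return best


def brute_force_closeness(g: nx.DiGraph, alpha: float) -> dict:
    """Reciprocal of summed brute-force distances over reachable targets."""
    out = {}
    for node in g.nodes:
        d = brute_force_distances(g, node, alpha)
        d.pop(node, None)
        total = sum(d.values())
        out[node] = 1.0 / total if total > 0 else 0.0
    return out


def bfs_hop_closeness(g: nx.DiGraph) -> dict:
    """Hop-count closeness from a hand-rolled BFS (the alpha = 0 limit)."""
    from collections import deque

    out = {}
    for node in g.nodes:
        dist = {node: 0}
        queue = deque([node])
        while queue:
            u = queue.popleft()
            for v in g.successors(u):
                if v != u and v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        dist.pop(node)
        total = sum(dist.values())
        out[node] = 1.0 / total if total > 0 else 0.0
    return out


def random_digraph(rng: np.random.Generator, n_max: int = 7,
                   p: float = 0.35) -> nx.DiGraph:
    """Random weighted digraph with <= n_max nodes and positive weights."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v, weight=float(rng.uniform(0.2, 50.0)))
    return g


@pytest.fixture
def oracle():
    """Bundle of independent reference implementations."""
    return {
        "distances": brute_force_distances,
        "closeness": brute_force_closeness,
        "bfs_closeness": bfs_hop_closeness,
        "random_digraph": random_digraph,
    }


# ---------------------------------------------------------------------------
# flow-table fixtures


def constant_shares(years, mapping) -> dict:
    return {y: dict(mapping) for y in years}


@pytest.fixture
def small_config() -> GeneratorConfig:
    """Three-year toy conditions: a handful of actors, seed 7."""
    years = range(1990, 1993)
    return GeneratorConfig(
        years=(1990, 1992),
        n_recipients=4,
        growth_schedule={
            "PUBLIC": {y: 3 for y in years},
            "PRIVATE": {y: 1 for y in years},
            "CSO": {1990: 2, 1991: 3, 1992: 3},
            "PPP": {y: 0 for y in years},
        },
        annual_total={y: 1e7 for y in years},
        source_share_schedule=constant_shares(
            years, {"PUBLIC": 0.7, "PRIVATE": 0.1, "CSO": 0.2, "PPP": 0.0}),
        channel_share_schedule=constant_shares(
            years, {"PUBLIC": 0.6, "PRIVATE": 0.1, "CSO": 0.3, "PPP": 0.0}),
        single_area_prob=0.5,
        n_health_areas=6,
        unspecified_rate=0.05,
        hybrid_recipient_donor_rate=0.25,
        records_per_actor=6,
        seed=7,
    ).validate()


@pytest.fixture
def tiny_flows() -> pd.DataFrame:
    """Hand-written two-record flow table (one source, one channel)."""
    return pd.DataFrame(
        [
            [2000, "a", "b", "UGA", "malaria", 5.0],
            [2000, "a", "b", "KEN", "malaria", 3.0],
        ],
        columns=["year", "source_id", "channel_id", "recipient_id",
                 "health_area", "amount_usd"],
    )


# Desk-scale default dataset is expensive enough to share across the session.


@pytest.fixture(scope="session")
def default_config_session() -> GeneratorConfig:
    return default_config_mdg_era()


@pytest.fixture(scope="session")
def default_flows(default_config_session) -> pd.DataFrame:
    return generate(default_config_session)


@pytest.fixture(scope="session")
def default_clean(default_flows) -> pd.DataFrame:
    return drop_unspecified(default_flows)


@pytest.fixture(scope="session")
def default_registry(default_config_session):
    return make_registry(default_config_session)
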