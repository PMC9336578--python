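"""Per-year directed weighted graphs built from cleaned DAH flow tables.

Three projections are supported, all as :class:`networkx.DiGraph` with a
``weight`` edge attribute holding summed constant-USD amounts:

* bipartite source -> channel (one edge per funding relationship);
* bipartite channel -> recipient country;
* a unimodal graph of all actors, where each record deposits its amount on
  both hops (source -> channel and channel -> recipient).

Edges always point in the direction money moves.  An actor active in
several roles is a single node; per-year roles are recorded in the
``roles`` node attribute (comma-joined, e.g. ``"source,channel"``).
Parallel flows between the same pair are pre-summed, so graphs are simple;
self-loops (an actor funding itself after canonicalization) are retained as
data but ignored by all metrics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .ingest import aggregate_flows
from .typology import ActorRegistry

__all__ = [
    "AnnualNetwork",
    "build_bipartite",
    "build_unimodal",
    "graph_series",
    "export_graph",
    "load_graph",
]

#: Annual snapshot graph; ``graph`` attributes carry ``year`` and
#: ``projection``.
AnnualNetwork = nx.DiGraph

_MODES = ("source_channel", "channel_recipient")


def _year_slice(flows: pd.DataFrame, year: int,
                health_area: str | None) -> pd.DataFrame:
    sel = flows.loc[flows["year"] == year]
    if health_area is not None:
        sel = sel.loc[sel["health_area"] == health_area]
    return sel


def _annotate(g: nx.DiGraph, roles: Mapping[str, set],
              registry: ActorRegistry | None) -> None:
    for node in g.nodes:
        g.nodes[node]["roles"] = ",".join(sorted(roles.get(node, ())))
        if registry is not None:
            actor = registry.resolve(node)
            g.nodes[node]["category"] = actor.category.value
            g.nodes[node]["subgroup"] = actor.subgroup


def build_bipartite(
    flows: pd.DataFrame,
    year: int,
    mode: str,
    registry: ActorRegistry | None = None,
    health_area: str | None = None,
) -> AnnualNetwork:
    """Build the bipartite projection for one year.

    ``mode`` is ``"source_channel"`` (edges source -> channel, amounts
    summed over recipients and health areas) or ``"channel_recipient"``
    (edges channel -> recipient, summed over sources and areas).  A year
    with no records yields an empty graph.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown bipartite mode {mode!r}; expected {_MODES}")
    u_col, v_col = (("source_id", "channel_id") if mode == "source_channel"
                    else ("channel_id", "recipient_id"))
    sel = _year_slice(flows, year, health_area)
    g = nx.DiGraph(year=year, projection=mode)
    roles: dict[str, set] = {}
    if not sel.empty:
        agg = aggregate_flows(sel, [u_col, v_col])
        for u, v, w in agg.itertuples(index=False):
            g.add_edge(u, v, weight=float(w))
        for node in sel[u_col].unique():
            g.add_node(node)
            roles.setdefault(node, set()).add(u_col.removesuffix("_id"))
        for node in sel[v_col].unique():
            g.add_node(node)
            roles.setdefault(node, set()).add(v_col.removesuffix("_id"))
    _annotate(g, roles, registry)
    return g


def build_unimodal(
    flows: pd.DataFrame,
    year: int,
    registry: ActorRegistry | None = None,
    health_area: str | None = None,
) -> AnnualNetwork:
    """Build the all-actors graph for one year.

    Every record contributes its amount to two directed edges,
    source -> channel and channel -> recipient; contributions to the same
    ordered pair are summed.  Total edge weight therefore equals twice the
    summed record amounts.
    """
    sel = _year_slice(flows, year, health_area)
    g = nx.DiGraph(year=year, projection="unimodal")
    roles: dict[str, set] = {}
    if not sel.empty:
        hop1 = sel.rename(columns={"source_id": "u", "channel_id": "v"})
        hop2 = sel.rename(columns={"channel_id": "u", "recipient_id": "v"})
        both = pd.concat([hop1[["u", "v", "amount_usd"]],
                          hop2[["u", "v", "amount_usd"]]])
        agg = both.loc[both["amount_usd"] > 0].groupby(
            ["u", "v"], as_index=False, sort=True)["amount_usd"].sum()
        for u, v, w in agg.itertuples(index=False):
            g.add_edge(u, v, weight=float(w))
        for col, role in (("source_id", "source"), ("channel_id", "channel"),
                          ("recipient_id", "recipient")):
            for node in sel[col].unique():
                g.add_node(node)
                roles.setdefault(node, set()).add(role)
    _annotate(g, roles, registry)
    return g


def graph_series(
    flows: pd.DataFrame,
    years: Iterable[int] | None = None,
    projection: str = "unimodal",
    registry: ActorRegistry | None = None,
) -> dict[int, AnnualNetwork]:
    """One graph per year; years absent from the data yield empty graphs.

    ``years`` defaults to the inclusive range spanned by the data.
    """
    if years is None:
        if flows.empty:
            return {}
        years = range(int(flows["year"].min()), int(flows["year"].max()) + 1)
    if projection == "unimodal":
        return {y: build_unimodal(flows, y, registry) for y in years}
    return {y: build_bipartite(flows, y, projection, registry) for y in years}


def export_graph(network: AnnualNetwork, path: str | Path,
                 fmt: str | None = None) -> Path:
    """Write a graph as GEXF, GraphML or an edge-list CSV.

    ``fmt`` is one of ``gexf``, ``graphml``, ``csv`` (inferred from the
    path suffix when omitted).  Node attributes and edge weights round-trip
    losslessly through the XML formats; the CSV keeps only
    ``year,from,to,weight_usd``.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "gexf":
        nx.write_gexf(network, path)
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "csv":
        year = network.graph.get("year", "")
        rows = [(year, u, v, d["weight"])
                for u, v, d in network.edges(data=True)]
        pd.DataFrame(rows, columns=["year", "from", "to", "weight_usd"]).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; "
                         "expected gexf, graphml or csv")
    return path


def load_graph(path: str | Path, fmt: str | None = None) -> AnnualNetwork:
    """Re-import a graph written by :func:`export_graph` (GEXF/GraphML)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "gexf":
        g = nx.read_gexf(path)
    elif fmt == "graphml":
        g = nx.read_graphml(path)
    else:
        raise ValueError(f"cannot re-import format {fmt!r}")
    return nx.DiGraph(g)
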