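"""Descriptive outputs of the DAH landscape analysis.

Annual totals, node/edge counts, proportional category shares of source and
channel totals, the single-health-area CSO statistic, top-N ranking tables
and the end-to-end pipeline (generate -> clean -> build -> metrics ->
report) with a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .centrality import (
    MetricConfig,
    average_closeness_by_type,
    channel_degree_centrality,
    generalized_closeness,
    in_degree,
    out_degree,
    rank_actors,
)
from .ingest import aggregate_flows, drop_unspecified, write_flow_table
from .networks import build_bipartite, export_graph, graph_series
from .synthetic import GeneratorConfig, generate, make_registry
from .typology import ActorRegistry, Category

logger = logging.getLogger(__name__)

__all__ = [
    "annual_totals",
    "node_edge_counts",
    "proportional_distribution",
    "single_health_area_share",
    "top_n",
    "landscape_summary",
    "centrality_table",
    "run_all",
]


def annual_totals(flows: pd.DataFrame) -> dict[int, float]:
    """Total disbursed USD per year, each record counted once."""
    if flows.empty:
        return {}
    grouped = flows.groupby("year")["amount_usd"].sum()
    return {int(y): float(v) for y, v in grouped.items()}


def node_edge_counts(series: dict[int, nx.DiGraph]) -> pd.DataFrame:
    """Per-year node and edge counts of a graph series."""
    return pd.DataFrame(
        [(y, series[y].number_of_nodes(), series[y].number_of_edges())
         for y in sorted(series)],
        columns=["year", "n_nodes", "n_edges"],
    )


def _attach_category(flows: pd.DataFrame, id_col: str,
                     registry: ActorRegistry) -> pd.Series:
    return flows[id_col].map(lambda i: registry.category_of(i).value)


def proportional_distribution(
    flows: pd.DataFrame,
    registry: ActorRegistry,
    role: str,
) -> pd.DataFrame:
    """Category shares of annual totals by functional role.

    ``role="source"`` attributes each record's amount to its source actor's
    category; ``role="channel"`` to the channel's.  Either way each record
    is counted exactly once, so shares per year sum to 1.
    """
    if role not in ("source", "channel"):
        raise ValueError(f"role must be 'source' or 'channel', got {role!r}")
    if flows.empty:
        return pd.DataFrame(columns=["year", "category", "share"])
    work = flows[["year", "amount_usd"]].copy()
    work["category"] = _attach_category(flows, f"{role}_id", registry)
    agg = aggregate_flows(work, ["year", "category"])
    totals = agg.groupby("year")["amount_usd"].transform("sum")
    agg["share"] = agg["amount_usd"] / totals
    return agg[["year", "category", "share"]].reset_index(drop=True)


def single_health_area_share(
    flows: pd.DataFrame,
    registry: ActorRegistry,
    years: tuple[int, int] | None = None,
) -> tuple[int, float | None]:
    """Count and fraction of CSO channels funding exactly one health area.

    Pooled over all years by default (restrict with ``years``); the
    denominator is the set of CSO-category actors that ever appear in the
    channel role within the window.  Returns ``(0, None)`` with a warning
    when no CSO channels exist.
    """
    sel = flows
    if years is not None:
        sel = sel.loc[sel["year"].between(years[0], years[1])]
    if sel.empty:
        logger.warning("no records in window; no CSO channels to assess")
        return 0, None
    is_cso = _attach_category(sel, "channel_id", registry) == Category.CSO.value
    cso = sel.loc[is_cso]
    if cso.empty:
        logger.warning("no CSO channels in window")
        return 0, None
    n_areas = cso.groupby("channel_id")["health_area"].nunique()
    count = int((n_areas == 1).sum())
    return count, count / len(n_areas)


def top_n(
    table: pd.DataFrame,
    year: int,
    metric: str,
    n: int,
    category: str | None = None,
    registry: ActorRegistry | None = None,
) -> pd.DataFrame:
    """First ``n`` actors by rank for one (year, metric) group.

    With ``category`` (and a registry to resolve it) the listing is
    restricted to that actor category, keeping each actor's rank amongst
    all actors in a ``rank_overall`` column alongside the within-category
    ordering.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    sel = table.loc[(table["year"] == year) & (table["metric"] == metric)]
    sel = sel.sort_values("rank")
    if category is not None:
        if registry is None:
            raise ValueError("category filter requires a registry")
        keep = sel["actor_id"].map(
            lambda i: registry.category_of(i).value) == category
        sel = sel.loc[keep].rename(columns={"rank": "rank_overall"})
        sel = sel.reset_index(drop=True)
        sel.insert(len(sel.columns), "rank_within", range(1, len(sel) + 1))
    return sel.head(n).reset_index(drop=True)


def landscape_summary(
    flows: pd.DataFrame,
    registry: ActorRegistry,
    series: dict[int, nx.DiGraph],
) -> pd.DataFrame:
    """Wide per-year summary: totals, counts and per-category shares."""
    totals = annual_totals(flows)
    counts = node_edge_counts(series).set_index("year")
    rows = []
    shares = {
        role: proportional_distribution(flows, registry, role)
        .pivot(index="year", columns="category", values="share")
        for role in ("source", "channel")
    }
    for year in sorted(totals):
        row: dict = {
            "year": year,
            "total_dah_usd": totals[year],
            "n_actors": int(counts.loc[year, "n_nodes"]) if year in counts.index else 0,
            "n_edges": int(counts.loc[year, "n_edges"]) if year in counts.index else 0,
        }
        for role in ("source", "channel"):
            for cat in Category:
                if cat is Category.UNKNOWN:
                    continue
                pivot = shares[role]
                val = (float(pivot.loc[year, cat.value])
                       if year in pivot.index and cat.value in pivot.columns
                       and pd.notna(pivot.loc[year, cat.value]) else 0.0)
                row[f"{role}_share_{cat.value.lower()}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def centrality_table(
    flows: pd.DataFrame,
    registry: ActorRegistry,
    config: MetricConfig = MetricConfig(),
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Long-format (year, actor_id, metric, value, rank) over all years.

    Degrees come from the bipartite projections (source out-degree, channel
    in-degree from the source->channel graph; recipient in-degree and the
    channel degree centrality from both), closeness from the unimodal graph.
    """
    if years is None:
        years = sorted(flows["year"].unique())
    uni = graph_series(flows, years, "unimodal", registry)
    parts = []
    for year in years:
        sc = build_bipartite(flows, year, "source_channel", registry)
        cr = build_bipartite(flows, year, "channel_recipient", registry)
        parts.append(rank_actors(out_degree(sc), year, "out_degree"))
        parts.append(rank_actors(in_degree(cr), year, "in_degree"))
        parts.append(rank_actors(channel_degree_centrality(sc, cr), year,
                                 "channel_degree"))
        parts.append(rank_actors(generalized_closeness(uni[year], config),
                                 year, "closeness"))
    return pd.concat(parts, ignore_index=True)


def run_all(
    config: GeneratorConfig,
    outdir: str | Path,
    metric_config: MetricConfig = MetricConfig(),
    export_years: list[int] | None = None,
) -> dict[str, Path]:
    """Full pipeline: generate, clean, build, measure, report.

    Writes the synthetic dataset, the landscape summary, the full
    centrality table, per-metric ranking tables for the first, middle and
    last years, the top-CSO closeness table, GEXF exports of the unimodal
    graph for selected years, and a JSON manifest (seed, config hash,
    versions).  All outputs are deterministic for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    flows_raw = generate(config)
    registry = make_registry(config)
    flows = drop_unspecified(flows_raw)
    series = graph_series(flows, list(config.year_range), "unimodal", registry)

    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, fname: str) -> None:
        paths[name] = outdir / fname
        df.to_csv(paths[name], index=False, float_format="%.10g")

    paths["flows"] = outdir / "flows.csv"
    write_flow_table(flows_raw, paths["flows"])
    paths["actors"] = outdir / "actors.csv"
    registry.to_csv(paths["actors"])
    paths["config"] = outdir / "config.yaml"
    config.to_yaml(paths["config"])

    _write("landscape", landscape_summary(flows, registry, series),
           "landscape_summary.csv")
    table = centrality_table(flows, registry, metric_config)
    _write("centrality", table, "centrality.csv")

    y0, y1 = config.years
    report_years = sorted({y0, (y0 + y1) // 2, y1})
    for year in report_years:
        for metric in ("out_degree", "in_degree", "channel_degree", "closeness"):
            _write(f"rankings_{year}_{metric}",
                   top_n(table, year, metric, 10),
                   f"rankings_{year}_{metric}.csv")
    _write("top_cso_closeness",
           top_n(table, y1, "closeness", 25, category="CSO", registry=registry),
           "top_cso_closeness.csv")

    for year in (export_years if export_years is not None else [y0, y1]):
        paths[f"graph_{year}"] = export_graph(
            series[year], outdir / f"unimodal_{year}.gexf")

    manifest = {
        "package": "dahnet",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "python": sys.version.split()[0],
        "n_records": int(len(flows_raw)),
        "n_records_clean": int(len(flows)),
        "metric_config": {
            "alpha": metric_config.alpha,
            "direction": metric_config.direction,
            "unreachable_policy": metric_config.unreachable_policy,
        },
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
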