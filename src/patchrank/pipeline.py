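"""The five-stage ranking pipeline and its report writers.

Stages: (1) build the patch graph, (2) census the connected components,
(3) detect cut nodes and attach site distances, (4) simulate each single
cut-node removal to obtain C_A and C_S, (5) convert metrics to strictly-
less percentile scores, sum them into the combined score and emit the
priority ranking, with normalized betweenness kept as a comparison column.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

import pandas as pd

from . import io as graph_io
from .centrality import betweenness
from .config import ConfigError, RunConfig
from .graph import PatchGraph, connected_components, find_cut_nodes
from .removal import removal_metrics_all
from .scoring import (
    CorrelationReport,
    MetricDistribution,
    build_ranking,
    correlation_report,
)

log = logging.getLogger("patchrank")

__all__ = ["RankResult", "run_rank", "write_reports"]


@dataclass
class RankResult:
    """Everything a ranking run produced, ready for report rendering."""

    config: RunConfig
    graph: PatchGraph
    metrics: pd.DataFrame           # node_id, C_A, C_S, [D], C_B_norm, ...
    ranking: pd.DataFrame           # scored + ordered
    distributions: dict[str, MetricDistribution]
    correlation: CorrelationReport | None
    counts: dict[str, int]
    layer: "object | None" = None   # PatchLayer when spatial input was used


def _load_graph(config: RunConfig):
    layer = None
    if config.patches:
        from .spatial import polygons_to_graph, read_patch_layer

        layer = read_patch_layer(config.patches)
        g = polygons_to_graph(layer, adjacency=config.adjacency)
    elif config.graphml:
        g = graph_io.read_graphml(config.graphml)
    else:
        g = graph_io.read_edge_csv(config.edges)
    return g, layer


def _load_distances(config: RunConfig, layer) -> Mapping[Hashable, float] | None:
    if config.patches and config.sites:
        from .spatial import min_site_distance, read_site_set

        return min_site_distance(layer, read_site_set(config.sites))
    if config.distances:
        dist: dict[Hashable, float] = {}
        with open(config.distances, newline="") as fh:
            for row in csv.DictReader(fh):
                dist[graph_io._coerce(row["node_id"])] = float(row["D"])
        return dist
    return None


def run_rank(config: RunConfig) -> RankResult:
    """Execute the full pipeline for one configuration."""
    metric_set = config.resolved_metrics()  # fail fast on D without source

    log.info("stage 1: building graph")
    g, layer = _load_graph(config)
    parts = connected_components(g)
    log.info(
        "stage 2: %d nodes, %d edges, %d components",
        g.n_nodes, g.n_edges, len(parts),
    )

    cut = sorted(find_cut_nodes(g), key=lambda v: (type(v).__name__, v))
    log.info("stage 3: %d cut nodes (%.2f%% of nodes)",
             len(cut), 100.0 * len(cut) / g.n_nodes if g.n_nodes else 0.0)
    if not cut:
        log.warning("no cut nodes found; ranking is empty")

    distances = _load_distances(config, layer)
    if "D" in metric_set and distances is None:
        raise ConfigError("metric D requested but no distance source available")

    log.info("stage 4: simulating removals")
    metrics = removal_metrics_all(g, cut)

    cb = betweenness(g, scope=config.normalization)
    metrics = metrics.merge(
        cb.rename(columns={"normalized": "C_B_norm", "raw": "C_B_raw"}),
        on="node_id", how="left",
    )
    metrics["C_B"] = metrics["C_B_norm"]
    if distances is not None:
        missing = [v for v in metrics["node_id"] if v not in distances]
        if missing and "D" in metric_set:
            raise ConfigError(f"no site distance for node(s): {missing[:5]}")
        metrics["D"] = [distances.get(v) for v in metrics["node_id"]]

    log.info("stage 5: percentile scoring and ranking")
    ranking = build_ranking(metrics, metric_set, noise_filter=config.noise_filter)
    if len(ranking):
        ranking["C_B_rank"] = (
            ranking["C_B_norm"].rank(ascending=False, method="min").astype(int)
        )

    distributions = {
        m: MetricDistribution.from_values(m, ranking[m]) if len(ranking) else
        MetricDistribution(m, {}, 0)
        for m in metric_set
    }
    corr = None
    if len(ranking) >= 3:
        corr = correlation_report(ranking["combined"], ranking["C_B_norm"])

    counts = {
        "nodes": g.n_nodes,
        "edges": g.n_edges,
        "components": len(parts),
        "cut_nodes": len(cut),
        "ranked": len(ranking),
    }
    return RankResult(config, g, metrics, ranking, distributions, corr, counts, layer)


def write_reports(result: RankResult, outdir: str | Path | None = None) -> list[Path]:
    """Render the run into deterministic CSV/JSON artifacts.

    Emits ``ranking.csv`` (per cut node: raw value and percentile per
    metric, combined score, betweenness and its rank), one
    ``hist_<metric>.csv`` per scored metric (value, occurrences,
    percentile), ``correlation.json``, ``run.json`` (config echo plus
    stage counts) and, when the run started from polygons,
    ``ranking.geojson`` with the scores joined onto the patch geometries.
    """
    out = Path(outdir if outdir is not None else result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    nd = result.config.rounding
    written: list[Path] = []
    metric_set = list(result.distributions)

    cols = ["node_id"]
    for m in metric_set:
        cols += [m, f"{m}_pctl"]
    cols += ["combined", "rank", "C_B_norm", "C_B_rank"]
    rank_df = result.ranking.copy()
    for c in cols:
        if c not in rank_df.columns:
            rank_df[c] = None
    rank_df = rank_df[cols]
    for c in rank_df.columns:
        if rank_df[c].dtype.kind == "f":
            digits = 5 if c == "C_B_norm" else nd
            rank_df[c] = rank_df[c].round(digits)
    p = out / "ranking.csv"
    rank_df.to_csv(p, index=False)
    written.append(p)

    for m, dist in result.distributions.items():
        p = out / f"hist_{m}.csv"
        tab = dist.table()
        tab["percentile"] = pd.to_numeric(tab["percentile"]).round(5)
        tab.to_csv(p, index=False)
        written.append(p)

    p = out / "correlation.json"
    p.write_text(json.dumps(
        result.correlation.as_dict() if result.correlation else None, indent=1
    ))
    written.append(p)

    p = out / "run.json"
    p.write_text(json.dumps(
        {"config": result.config.as_dict(), "counts": result.counts,
         "metric_set": metric_set},
        indent=1, default=str,
    ))
    written.append(p)

    if result.layer is not None:
        from .spatial import write_patch_layer

        extra = {
            row["node_id"]: {
                "combined": round(float(row["combined"]), nd),
                "rank": int(row["rank"]),
                "is_cut": True,
            }
            for _, row in result.ranking.iterrows()
        }
        p = out / "ranking.geojson"
        write_patch_layer(result.layer, p, extra_properties=extra)
        written.append(p)
    return written
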