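"""PPI-based candidate prioritization.

Candidates and known disease genes are placed on a score-thresholded,
undirected protein-interaction graph; candidates are kept by unweighted
hop distance to the known set ("shortest links"), direct interactors
(distance <= 1) by default.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


def build_graph(
    edges: pd.DataFrame,
    min_score: float = 0.4,
    extra_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Undirected PPI graph from a (gene_a, gene_b, score) frame.

    Edges below ``min_score`` are dropped; duplicate undirected edges keep
    the maximum score; self-loops are ignored.  ``extra_nodes`` (e.g. query
    genes with no surviving interaction) are retained with degree 0.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        if row.gene_a == row.gene_b:
            continue
        if row.score < min_score:
            continue
        if g.has_edge(row.gene_a, row.gene_b):
            g[row.gene_a][row.gene_b]["score"] = max(g[row.gene_a][row.gene_b]["score"], row.score)
        else:
            g.add_edge(row.gene_a, row.gene_b, score=float(row.score))
    g.add_nodes_from(extra_nodes)
    return g


def shortest_distances(graph: nx.Graph, sources: Iterable[str]) -> dict[str, float]:
    """Multi-source unweighted BFS hop distance to the nearest source.

    Sources absent from the graph are logged and skipped; unreachable
    nodes get ``inf``.  An empty effective source set is a hard error.
    """
    sources = set(sources)
    missing = sources - set(graph.nodes)
    if missing:
        log.warning("source genes absent from graph, skipped: %s", sorted(missing)[:10])
    effective = sources & set(graph.nodes)
    if not effective:
        raise ValueError("no source genes present in the graph")
    dist = nx.multi_source_dijkstra_path_length(graph, effective, weight=None)
    return {node: dist.get(node, math.inf) for node in graph.nodes}


def prioritize(
    candidates: pd.DataFrame,
    graph: nx.Graph,
    known_set: Iterable[str],
    max_distance: float = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep candidate genes within ``max_distance`` hops of the known set.

    ``candidates`` is the integrated table (one row per gene with criterion
    flags); rows whose gene is missing from the graph are excluded and
    logged.  Returns the kept table (with a ``ppi_distance`` column) and
    the induced subnetwork edge list over kept candidates plus known genes
    for plotting.
    """
    known = set(known_set)
    dist = shortest_distances(graph, known)
    in_graph = candidates["gene"].isin(dist)
    absent = candidates.loc[~in_graph, "gene"].tolist()
    if absent:
        log.info("candidates absent from PPI graph excluded: %s", absent[:10])
    kept = candidates[in_graph].copy()
    kept["ppi_distance"] = [dist[g] for g in kept["gene"]]
    reachable = kept["ppi_distance"].map(math.isfinite)
    kept = kept[reachable & (kept["ppi_distance"] <= max_distance)].reset_index(drop=True)

    sub_nodes = set(kept["gene"]) | (known & set(graph.nodes))
    sub = graph.subgraph(sub_nodes)
    sub_edges = pd.DataFrame(
        [
            {"gene_a": u, "gene_b": v, "score": d.get("score", float("nan"))}
            for u, v, d in sub.edges(data=True)
        ],
        columns=["gene_a", "gene_b", "score"],
    )
    return kept, sub_edges
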