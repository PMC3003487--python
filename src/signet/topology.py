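"""Undirected topology statistics on the simple projection of a network.

All metrics follow the NetworkAnalyzer conventions used for curated
regulation networks: the typed multigraph is treated as undirected with
parallel links collapsed; nodes of degree < 2 contribute a local clustering
coefficient of 0 to the network average; the characteristic path length
averages shortest-path distances over *connected* unordered node pairs
(disconnected pairs are excluded, not treated as infinite) and the diameter
is the largest finite distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import networkx as nx

from .errors import SignetError, UndefinedMetricsError
from .model import RegNetwork, SimpleGraph, simple_projection


def _to_nx(g: SimpleGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(g.nodes)
    G.add_edges_from(g.edges)
    return G


def local_clustering(g: SimpleGraph, node: str) -> float:
    """Local clustering coefficient 2*e_N / (k*(k-1)); 0 for degree < 2."""
    if node not in g.nodes:
        raise SignetError(f"unknown node {node!r}")
    return float(nx.clustering(_to_nx(g), node))


def path_metrics(g: SimpleGraph) -> Tuple[float, int]:
    """Characteristic path length and diameter over connected pairs.

    Raises :class:`~signet.errors.UndefinedMetricsError` for edgeless
    graphs, where no pair is connected.
    """
    G = _to_nx(g)
    if G.number_of_edges() == 0:
        raise UndefinedMetricsError("path metrics are undefined on an edgeless graph")
    total = 0
    count = 0
    diameter = 0
    for comp in nx.connected_components(G):
        if len(comp) < 2:
            continue
        sub = G.subgraph(comp)
        for src, dists in nx.all_pairs_shortest_path_length(sub):
            for tgt, d in dists.items():
                if src < tgt:  # each unordered pair once
                    total += d
                    count += 1
                    if d > diameter:
                        diameter = d
    return total / count, diameter


@dataclass(frozen=True)
class TopologySummary:
    """Network-level statistics; path/clustering fields are None when undefined."""

    n_nodes: int
    n_link_records: int
    n_simple_edges: int
    avg_degree: Optional[float]
    clustering_coefficient: Optional[float]
    characteristic_path_length: Optional[float]
    diameter: Optional[int]
    n_components: int


def topology_summary(
    net: RegNetwork, *, include_low_degree_in_clustering: bool = True
) -> TopologySummary:
    """Compute all summary statistics on the simple undirected projection.

    ``n_link_records`` counts raw curated link records (the multiset);
    every other quantity is computed on the collapsed simple graph.  The
    clustering average includes degree-<2 nodes as zeros by default; set
    ``include_low_degree_in_clustering=False`` to average over degree-≥2
    nodes only.
    """
    g = simple_projection(net)
    G = _to_nx(g)
    n = G.number_of_nodes()
    m = G.number_of_edges()
    avg_degree = 2 * m / n if n else None
    if n == 0:
        clustering = None
    else:
        per_node = nx.clustering(G)
        if not include_low_degree_in_clustering:
            per_node = {v: c for v, c in per_node.items() if G.degree(v) >= 2}
        clustering = (
            sum(per_node.values()) / len(per_node) if per_node else 0.0
        )
    try:
        cpl, diameter = path_metrics(g)
    except UndefinedMetricsError:
        cpl, diameter = None, None
    return TopologySummary(
        n_nodes=n,
        n_link_records=len(net.links),
        n_simple_edges=m,
        avg_degree=avg_degree,
        clustering_coefficient=clustering,
        characteristic_path_length=cpl,
        diameter=diameter,
        n_components=nx.number_connected_components(G),
    )
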