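"""Confidence-filtered interaction graph and per-node topology metrics.

Eight metrics are computed per node: average shortest path length (over
the node's reachable set), closeness (its reciprocal), normalized
betweenness, stress (raw shortest-path counts), degree, neighbourhood
connectivity, clustering coefficient and topological coefficient.
Betweenness is normalized by (N-1)(N-2)/2 with N the whole-graph node
count; genes absent from the graph or isolated get all-zero metrics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "NodeMetrics",
    "build_graph",
    "compute_metrics",
    "compute_all_metrics",
    "metrics_for_genes",
    "read_edge_list",
    "read_gene_protein_map",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "avg_shortest_path",
    "closeness",
    "betweenness",
    "stress",
    "degree",
    "neighbourhood_connectivity",
    "clustering_coefficient",
    "topological_coefficient",
)


@dataclass(frozen=True)
class NodeMetrics:
    avg_shortest_path: float = 0.0
    closeness: float = 0.0
    betweenness: float = 0.0
    stress: int = 0
    degree: int = 0
    neighbourhood_connectivity: float = 0.0
    clustering_coefficient: float = 0.0
    topological_coefficient: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


_ZERO = NodeMetrics()


def build_graph(
    edge_list: Iterable[tuple[str, str, float]], min_confidence: float = 0.63
) -> nx.Graph:
    """Build the undirected interaction graph from scored edges.

    Edges are kept when confidence is strictly above ``min_confidence``;
    duplicates collapse to the maximum confidence and self-loops are
    dropped.
    """
    best: dict[tuple[str, str], float] = {}
    for row in edge_list:
        try:
            a, b, conf = row[0], row[1], float(row[2])
        except (IndexError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge row: {row!r}") from exc
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        best[key] = max(best.get(key, conf), conf)
    graph = nx.Graph()
    for (a, b), conf in best.items():
        if conf > min_confidence:
            graph.add_edge(a, b, confidence=conf)
    return graph


def _betweenness_stress(graph: nx.Graph) -> tuple[dict, dict]:
    """Brandes-style accumulation of normalized betweenness and raw stress.

    Shortest-path counts use exact integer arithmetic; betweenness is
    normalized by (N-1)(N-2)/2 over the whole graph.
    """
    betweenness = dict.fromkeys(graph, 0.0)
    stress = dict.fromkeys(graph, 0)
    for source in graph:
        stack: list = []
        preds: dict = {v: [] for v in graph}
        sigma = dict.fromkeys(graph, 0)
        sigma[source] = 1
        dist = dict.fromkeys(graph, -1)
        dist[source] = 0
        queue = [source]
        while queue:
            next_queue = []
            for v in queue:
                stack.append(v)
                for w in graph[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        next_queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = next_queue
        delta = dict.fromkeys(graph, 0.0)  # fractional dependency (betweenness)
        downstream = dict.fromkeys(graph, 0)  # shortest-DAG continuations (stress)
        for w in reversed(stack):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
                downstream[v] += 1 + downstream[w]
            if w != source:
                betweenness[w] += delta[w]
                stress[w] += sigma[w] * downstream[w]
    # undirected: every pair counted twice (once per endpoint as source)
    n = graph.number_of_nodes()
    norm = (n - 1) * (n - 2) if n > 2 else 1
    for v in graph:
        betweenness[v] /= norm
        stress[v] //= 2
    return betweenness, stress


def compute_all_metrics(graph: nx.Graph) -> dict[str, NodeMetrics]:
    """All eight metrics for every node of the graph."""
    if graph.number_of_nodes() == 0:
        return {}
    betweenness, stress = _betweenness_stress(graph)
    clustering = nx.clustering(graph)
    out: dict[str, NodeMetrics] = {}
    for node in graph:
        degree = graph.degree(node)
        if degree == 0:
            out[node] = _ZERO
            continue
        lengths = nx.single_source_shortest_path_length(graph, node)
        reachable = [d for m, d in lengths.items() if m != node]
        avg_sp = sum(reachable) / len(reachable) if reachable else 0.0
        closeness = 1.0 / avg_sp if avg_sp > 0 else 0.0
        neighbours = list(graph[node])
        nbr_conn = sum(graph.degree(m) for m in neighbours) / degree
        out[node] = NodeMetrics(
            avg_shortest_path=avg_sp,
            closeness=closeness,
            betweenness=betweenness[node],
            stress=int(stress[node]),
            degree=degree,
            neighbourhood_connectivity=nbr_conn,
            clustering_coefficient=clustering[node],
            topological_coefficient=_topological_coefficient(graph, node),
        )
    return out


def _topological_coefficient(graph: nx.Graph, node) -> float:
    degree = graph.degree(node)
    if degree < 2:
        return 0.0
    neighbours = set(graph[node])
    shared: dict = {}
    for nbr in neighbours:
        for second in graph[nbr]:
            if second != node:
                shared[second] = shared.get(second, 0) + 1
    if not shared:
        return 0.0
    total = 0.0
    for partner, count in shared.items():
        j = count + (1 if graph.has_edge(node, partner) else 0)
        total += j / degree
    return total / len(shared)


def compute_metrics(graph: nx.Graph, node) -> NodeMetrics:
    """Metrics for a single node (absent node gets the all-zero record)."""
    if node not in graph:
        return _ZERO
    return compute_all_metrics(graph)[node]


def metrics_for_genes(
    graph: nx.Graph, gene_to_protein: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene metric table; unmapped or absent genes get all zeros."""
    all_metrics = compute_all_metrics(graph)
    rows = {}
    for gene, protein in gene_to_protein.items():
        rows[gene] = all_metrics.get(protein, _ZERO).as_dict()
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))
    frame.index.name = "gene_id"
    return frame


def read_edge_list(path) -> list[tuple[str, str, float]]:
    """Read a scored edge list TSV (id_a, id_b, confidence), with header."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append((row["id_a"], row["id_b"], float(row["confidence"])))
    return out


def read_gene_protein_map(path) -> dict[str, str]:
    """Read a gene-to-protein map TSV (gene_id, protein_id), with header."""
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["gene_id"]] = row["protein_id"]
    return out
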