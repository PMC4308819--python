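"""Cluster-transition graphs and binding-route extraction.

After mesostate clustering, each trajectory becomes a sequence of cluster
labels. Transitions between distinct clusters are counted (within each
trajectory, never across trajectory boundaries) and assembled into an
undirected graph whose edge weights are the negative log relative
transition frequency, ``w_ij = -ln(n_ij / N_tot)`` — frequently used edges
are cheap, rare ones expensive, so shortest paths trace the statistically
dominant binding routes. Note the normalization by the total inter-cluster
count ``N_tot``: the un-normalized ``-ln(n_ij)`` would be negative for any
edge crossed more than once, which Dijkstra cannot handle; dividing by
``N_tot`` keeps the ordering of edges by count while making all weights
non-negative.

Ranked, mutually independent routes are obtained by iterating: find the
shortest source-to-sink path, record it, delete its interior nodes (and the
edges it used), repeat until the sink is unreachable. Returned routes share
no intermediate cluster, so each is an independent mechanism.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TransitionGraph",
    "BindingPath",
    "build_transition_graph",
    "shortest_path",
    "extract_disjoint_paths",
]


@dataclass
class BindingPath:
    """One source-to-sink route over the transition graph."""

    nodes: list
    total_weight: float
    edge_counts: list[int]

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def interior(self) -> list:
        return self.nodes[1:-1]


@dataclass
class TransitionGraph:
    """Undirected transition-count graph over cluster ids.

    ``graph`` is a :class:`networkx.Graph` whose edges carry ``count``
    (symmetrized transition count) and ``weight`` (= -ln(count / N_tot)).
    ``annotations`` maps node ids to labels such as ``"out"`` (source) or
    ensemble names (sinks).
    """

    graph: nx.Graph
    n_total: int
    annotations: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def annotate(self, node, label: str) -> None:
        if node not in self.graph:
            raise KeyError(f"node {node!r} not in graph")
        self.annotations[node] = label
        self.graph.nodes[node]["annotation"] = label


def build_transition_graph(label_sequences, lag: int = 1) -> TransitionGraph:
    """Count inter-cluster transitions at the given lag and weight them.

    Transitions are counted within each sequence only; self-transitions are
    ignored; counts for (i, j) and (j, i) are pooled onto one undirected
    edge. A node is created for every label observed, so clusters without
    inter-cluster transitions still appear (isolated).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    sequences = [np.asarray(s) for s in label_sequences]
    if not sequences or any(s.size == 0 for s in sequences):
        raise ValueError("label sequences must be non-empty")
    counts: dict[tuple, int] = {}
    G = nx.Graph()
    cluster_sizes: dict = {}
    for seq in sequences:
        for lab, cnt in zip(*np.unique(seq, return_counts=True)):
            key = lab.item()
            cluster_sizes[key] = cluster_sizes.get(key, 0) + int(cnt)
        for a, b in zip(seq[:-lag], seq[lag:]):
            a, b = a.item(), b.item()
            if a == b:
                continue
            key = (a, b) if repr(a) <= repr(b) else (b, a)
            counts[key] = counts.get(key, 0) + 1
    for node, size in cluster_sizes.items():
        G.add_node(node, size=size)
    n_total = sum(counts.values())
    if n_total == 0:
        warnings.warn("all transitions are self-transitions; graph has no edges")
    for (a, b), n_ij in counts.items():
        G.add_edge(a, b, count=n_ij, weight=-math.log(n_ij / n_total))
    return TransitionGraph(graph=G, n_total=n_total)


def _as_nx(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, TransitionGraph) else graph


def shortest_path(graph, source, sink) -> BindingPath | None:
    """Minimum-weight route by Dijkstra; ``None`` if the sink is unreachable.

    Valid because all weights are non-negative. Ties between equal-weight
    alternatives break lexicographically (smallest node first), so results
    are order-independent and reproducible.
    """
    G = _as_nx(graph)
    if source not in G or sink not in G:
        raise KeyError("source and sink must be graph nodes")
    if source == sink:
        return BindingPath(nodes=[source], total_weight=0.0, edge_counts=[])
    dist: dict = {source: 0.0}
    pred: dict = {}
    done: set = set()
    heap: list = [(0.0, repr(source), source)]
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == sink:
            break
        for v, attrs in sorted(G[u].items(), key=lambda kv: repr(kv[0])):
            if v in done:
                continue
            nd = d + attrs["weight"]
            better = v not in dist or nd < dist[v] - 1e-15
            tie = v in pred and abs(nd - dist[v]) <= 1e-15 and repr(u) < repr(pred[v])
            if better or tie:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, repr(v), v))
    if sink not in done:
        return None
    nodes = [sink]
    while nodes[-1] != source:
        nodes.append(pred[nodes[-1]])
    nodes.reverse()
    counts = [G.edges[a, b].get("count", 0) for a, b in zip(nodes[:-1], nodes[1:])]
    return BindingPath(nodes=nodes, total_weight=dist[sink], edge_counts=counts)


def extract_disjoint_paths(graph, source, sinks) -> dict:
    """Ranked interior-node-disjoint routes from source to each sink.

    For each sink independently (on a fresh copy of the graph): find the
    shortest path, record it, delete its interior nodes and every edge it
    used, and repeat until the sink becomes unreachable. Successive route
    weights are non-decreasing, since deletions can only lengthen the
    remaining shortest path. Edge deletion (in addition to interior-node
    removal) prevents a direct source-sink edge from being returned twice.
    """
    G0 = _as_nx(graph)
    if source not in G0:
        raise KeyError(f"source {source!r} not in graph")
    result: dict = {}
    for sink in sinks:
        if sink not in G0:
            raise KeyError(f"sink {sink!r} not in graph")
        G = G0.copy()
        paths: list[BindingPath] = []
        while True:
            p = shortest_path(G, source, sink)
            if p is None or len(p) < 2:
                break
            paths.append(p)
            G.remove_edges_from(list(zip(p.nodes[:-1], p.nodes[1:])))
            G.remove_nodes_from(p.interior)
        result[sink] = paths
    return result
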