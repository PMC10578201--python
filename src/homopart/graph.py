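"""Thresholded similarity graph and restricted single-linkage clustering.

The graph holds one node per input sequence and one undirected edge per
"neighbor" pair — a pair whose identity strictly exceeds the partitioning
threshold. Edge weights are stored as distances d = 1 − identity; the
threshold undergoes the same conversion.

Clustering is agglomerative single linkage over the ascending-distance edge
stream, restricted so that no cluster ever exceeds the expected partition
size |S|/k nor the expected per-partition count |S_l|/k of any class label.
The resulting clusters are the atoms the partition assignment distributes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import networkx as nx

from .align import PairwiseResult
from .io import DISTANCE, EdgeListEntry
from .records import DatasetError, SequenceRecord


def identity_to_distance(identity: float) -> float:
    """Convert a pairwise identity in [0, 1] to a distance d = 1 − identity."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0, 1]")
    return 1.0 - identity


@dataclass
class SimilarityGraph:
    """Sequences plus their threshold-violating pairs.

    Invariant: every stored edge has distance strictly below
    ``threshold_distance`` (identity strictly above the identity threshold);
    edges are undirected, stored once, no self-edges.
    """

    graph: nx.Graph
    threshold_distance: float

    @property
    def identity_threshold(self) -> float:
        return 1.0 - self.threshold_distance

    @property
    def node_order(self) -> list[str]:
        return list(self.graph.nodes)

    def labels(self) -> dict[str, str]:
        return {n: d["label"] for n, d in self.graph.nodes(data=True)}

    def priorities(self) -> dict[str, bool]:
        return {n: d["priority"] for n, d in self.graph.nodes(data=True)}

    def edges(self) -> Iterable[tuple[str, str, float]]:
        """Edges in canonical endpoint order with their distances."""
        for u, v, d in self.graph.edges(data="distance"):
            if u > v:
                u, v = v, u
            yield u, v, d

    def sorted_edges(self) -> list[tuple[float, str, str]]:
        """Edges sorted by (distance, id_a, id_b) for deterministic iteration."""
        return sorted((d, u, v) for u, v, d in self.edges())


def build_graph(
    results: Iterable[Union[PairwiseResult, EdgeListEntry]],
    records: list[SequenceRecord],
    identity_threshold: float,
) -> SimilarityGraph:
    """Assemble the similarity graph from an alignment stream or edge list.

    All records become nodes (isolated ones included); an edge is kept iff
    its identity strictly exceeds ``identity_threshold`` — equivalently its
    distance is strictly below the converted threshold. Edges already
    expressed as distances are filtered by the distance mirror directly.
    """
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError(f"identity threshold {identity_threshold} not in (0, 1)")
    threshold_distance = identity_to_distance(identity_threshold)
    g = nx.Graph()
    for rec in records:
        g.add_node(rec.id, label=rec.label, priority=rec.priority)
    for item in results:
        if isinstance(item, EdgeListEntry) and item.value_kind == DISTANCE:
            dist = item.value
        elif isinstance(item, EdgeListEntry):
            dist = identity_to_distance(item.value)
        else:
            dist = identity_to_distance(item.identity)
        a, b = item.id_a, item.id_b
        if a not in g or b not in g:
            missing = a if a not in g else b
            raise DatasetError(f"edge references unknown sequence id {missing!r}")
        if dist < threshold_distance:
            g.add_edge(a, b, distance=dist)
    return SimilarityGraph(graph=g, threshold_distance=threshold_distance)


@dataclass
class ClusterState:
    """Clusters in emission order, with member lists and per-label counts."""

    clusters: list[list[str]]
    labels: dict[str, str]
    label_counts: list[Counter] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_counts:
            self.label_counts = [
                Counter(self.labels[m] for m in members) for members in self.clusters
            ]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def cluster_of(self) -> dict[str, int]:
        return {m: i for i, members in enumerate(self.clusters) for m in members}


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in self.parent}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, ra: str, rb: str) -> str:
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return ra


def restricted_single_linkage(sim: SimilarityGraph, k: int) -> ClusterState:
    """Single-linkage clustering capped at the expected partition sizes.

    Edges are consumed in ascending distance order (ties by canonical ids);
    a merge is refused whenever the combined cluster would exceed |S|/k
    sequences or |S_l|/k sequences of any label l (real-valued caps).
    Iteration stops at the first edge at or beyond the distance threshold —
    by construction the graph holds none, but a caller-supplied precomputed
    graph might.

    Cluster emission order: first-touch order over the sorted edge stream
    (the first processed edge mentioning any member, merged or not), with
    never-touched singletons appended in input order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = sim.labels()
    node_order = sim.node_order
    n = len(node_order)
    size_cap = n / k
    label_totals = Counter(labels.values())
    label_caps = {l: c / k for l, c in label_totals.items()}

    uf = _UnionFind(node_order)
    counts: dict[str, Counter] = {x: Counter({labels[x]: 1}) for x in node_order}
    first_touch: dict[str, int] = {}

    for idx, (dist, a, b) in enumerate(sim.sorted_edges()):
        if dist >= sim.threshold_distance:
            break
        ra, rb = uf.find(a), uf.find(b)
        touch = min(
            first_touch.get(ra, idx),
            first_touch.get(rb, idx),
        )
        first_touch[ra] = min(first_touch.get(ra, idx), idx)
        first_touch[rb] = min(first_touch.get(rb, idx), idx)
        if ra == rb:
            continue
        if uf.size[ra] + uf.size[rb] > size_cap:
            continue
        merged = counts[ra] + counts[rb]
        if any(merged[l] > label_caps[l] for l in merged):
            continue
        root = uf.union(ra, rb)
        other = rb if root == ra else ra
        counts[root] = merged
        del counts[other]
        first_touch[root] = touch

    members: dict[str, list[str]] = {}
    for node in node_order:  # input order inside each cluster
        members.setdefault(uf.find(node), []).append(node)

    touched = sorted(
        (r for r in members if r in first_touch), key=lambda r: first_touch[r]
    )
    untouched = [r for r in node_order if uf.find(r) == r and r not in first_touch]
    ordered_roots = touched + [r for r in untouched if r in members]

    clusters = [members[r] for r in ordered_roots]
    assert sum(len(c) for c in clusters) == n
    return ClusterState(clusters=clusters, labels=labels)


def connected_components(sim: SimilarityGraph) -> list[set[str]]:
    """Connected components of the similarity graph (networkx traversal)."""
    return [set(c) for c in nx.connected_components(sim.graph)]
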