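"""Assigning clusters to class-balanced partitions and building 3-way splits.

Clusters are distributed greedily in their emission order: each cluster goes
whole to the partition that currently holds the fewest sequences of the
cluster's most frequent label (ties: smallest partition, then lowest index).
Train/validation/test splits are built by first partitioning into n groups,
then merging the most inter-connected groups so that as few neighbor edges
as possible straddle the final split boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .graph import ClusterState, SimilarityGraph

#: Partition value for sequences dropped during separation.
REMOVED = None

TRAIN, TEST, VALIDATION = 0, 1, 2
SPLIT_NAMES = {TRAIN: "train", TEST: "test", VALIDATION: "validation"}


class PartitionError(ValueError):
    """Raised for invalid partitioning inputs."""


@dataclass
class PartitionAssignment:
    """Map from sequence id to partition index (or None once removed).

    Per-partition per-label counts are maintained incrementally by
    :meth:`move` and :meth:`remove`; :meth:`recomputed_counts` rebuilds them
    from scratch for consistency checks.
    """

    mapping: dict[str, Optional[int]]
    k: int
    labels: dict[str, str]
    cluster_of: Optional[dict[str, int]] = None
    _counts: list[Counter] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise PartitionError("k must be >= 1")
        bad = [p for p in self.mapping.values() if p is not None and not 0 <= p < self.k]
        if bad:
            raise PartitionError(f"partition index {bad[0]} outside 0..{self.k - 1}")
        if self._counts is None:
            self._counts = self.recomputed_counts()

    def recomputed_counts(self) -> list[Counter]:
        counts = [Counter() for _ in range(self.k)]
        for sid, p in self.mapping.items():
            if p is not None:
                counts[p][self.labels[sid]] += 1
        return counts

    @property
    def counts(self) -> list[Counter]:
        return self._counts

    def partition_sizes(self) -> list[int]:
        return [sum(c.values()) for c in self._counts]

    def retained_ids(self) -> list[str]:
        return [sid for sid, p in self.mapping.items() if p is not None]

    def removed_ids(self) -> list[str]:
        return [sid for sid, p in self.mapping.items() if p is None]

    def retention_fraction(self) -> float:
        return len(self.retained_ids()) / len(self.mapping)

    def move(self, sid: str, new_partition: int) -> None:
        old = self.mapping[sid]
        if old is None:
            raise PartitionError(f"cannot move removed sequence {sid!r}")
        self._counts[old][self.labels[sid]] -= 1
        self._counts[new_partition][self.labels[sid]] += 1
        self.mapping[sid] = new_partition

    def remove(self, sid: str) -> None:
        old = self.mapping[sid]
        if old is None:
            raise PartitionError(f"sequence {sid!r} already removed")
        self._counts[old][self.labels[sid]] -= 1
        self.mapping[sid] = REMOVED

    def copy(self) -> "PartitionAssignment":
        return PartitionAssignment(
            mapping=dict(self.mapping),
            k=self.k,
            labels=self.labels,
            cluster_of=self.cluster_of,
        )


def assign_clusters(clusters: ClusterState, k: int) -> PartitionAssignment:
    """Distribute clusters whole over k partitions, balancing class labels.

    Clusters are consumed in emission order; the target partition minimizes
    the current count of the cluster's most frequent label, with ties broken
    by smallest total partition size, then lowest partition index.
    """
    if k < 1:
        raise PartitionError("k must be >= 1")
    counts = [Counter() for _ in range(k)]
    sizes = [0] * k
    mapping: dict[str, Optional[int]] = {}
    for members, label_count in zip(clusters.clusters, clusters.label_counts):
        # most frequent label of the cluster; lexicographic tie-break
        top_label = min(label_count, key=lambda l: (-label_count[l], l))
        target = min(range(k), key=lambda p: (counts[p][top_label], sizes[p], p))
        for sid in members:
            mapping[sid] = target
        counts[target] += label_count
        sizes[target] += len(members)
    return PartitionAssignment(
        mapping=mapping,
        k=k,
        labels=clusters.labels,
        cluster_of=clusters.cluster_of(),
    )


@dataclass(frozen=True)
class SplitSpec:
    """Fractions for a train/validation/test split.

    ``n`` is the smallest partition count making both fractions integral
    sequence-group counts; ``k_train = n (1 − test − val)`` partitions are
    merged into the train split, ``k_test = n·test`` into the test split,
    and the remainder becomes validation.
    """

    test_fraction: float
    val_fraction: float
    max_n: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1 and 0 < self.val_fraction < 1):
            raise PartitionError("fractions must lie in (0, 1)")
        if self.test_fraction + self.val_fraction >= 1:
            raise PartitionError("test + validation fractions must be < 1")
        self.n  # force integrality check at construction

    @property
    def n(self) -> int:
        for n in range(1, self.max_n + 1):
            t, v = n * self.test_fraction, n * self.val_fraction
            if abs(t - round(t)) < 1e-9 and abs(v - round(v)) < 1e-9:
                return n
        raise PartitionError(
            f"no n <= {self.max_n} makes fractions "
            f"({self.test_fraction}, {self.val_fraction}) integral"
        )

    @property
    def k_test(self) -> int:
        return round(self.n * self.test_fraction)

    @property
    def k_val(self) -> int:
        return round(self.n * self.val_fraction)

    @property
    def k_train(self) -> int:
        k = self.n - self.k_test - self.k_val
        if k < 1:
            raise PartitionError("train split would receive no partitions")
        return k


def _cross_edge_counts(sim: SimilarityGraph, mapping: dict[str, int], n: int):
    """n×n symmetric matrix of neighbor-edge counts between partitions."""
    counts = [[0] * n for _ in range(n)]
    for u, v, _ in sim.edges():
        pu, pv = mapping[u], mapping[v]
        if pu != pv:
            counts[pu][pv] += 1
            counts[pv][pu] += 1
    return counts


def _greedy_connected_subset(counts, available: list[int], size: int) -> list[int]:
    """Pick `size` partitions greedily by maximum connectivity.

    Seed: the available partition with the largest total edge count into the
    other available partitions; then repeatedly add the partition sharing the
    most edges with the current selection. All ties go to the lowest index.
    """
    totals = {
        p: sum(counts[p][q] for q in available if q != p) for p in available
    }
    seed = min(available, key=lambda p: (-totals[p], p))
    chosen = [seed]
    remaining = [p for p in available if p != seed]
    while len(chosen) < size:
        link = {p: sum(counts[p][q] for q in chosen) for p in remaining}
        nxt = min(remaining, key=lambda p: (-link[p], p))
        chosen.append(nxt)
        remaining.remove(nxt)
    return chosen


def make_tvt_split(
    sim: SimilarityGraph, clusters: ClusterState, spec: SplitSpec
) -> PartitionAssignment:
    """Build a train/test/validation assignment (k = 3; 0/1/2 respectively).

    The data is first assigned to n partitions; the maximally connected
    k_train of them (by cross-partition neighbor-edge counts) merge into the
    train split, the maximally connected k_test of the remainder into the
    test split, and the rest becomes validation. Keeping well-connected
    partitions together minimizes the edges the subsequent separation phase
    must eliminate at split boundaries.
    """
    n = spec.n
    base = assign_clusters(clusters, n)
    counts = _cross_edge_counts(sim, base.mapping, n)
    all_parts = list(range(n))
    train_parts = set(_greedy_connected_subset(counts, all_parts, spec.k_train))
    rest = [p for p in all_parts if p not in train_parts]
    test_parts = set(_greedy_connected_subset(counts, rest, spec.k_test))
    mapping: dict[str, Optional[int]] = {}
    for sid, p in base.mapping.items():
        if p in train_parts:
            mapping[sid] = TRAIN
        elif p in test_parts:
            mapping[sid] = TEST
        else:
            mapping[sid] = VALIDATION
    return PartitionAssignment(
        mapping=mapping, k=3, labels=clusters.labels, cluster_of=base.cluster_of
    )
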