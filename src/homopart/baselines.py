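"""Classic homology-reduction baselines: Hobohm 1/2 and greedy-min.

Reduction discards sequences until no two remaining ones are neighbors
(identity above the threshold) — it finds an independent set in the
similarity graph, keeping roughly one representative per homology cluster.
Partitioning, by contrast, keeps whole clusters together, so on clustered
data it retains far more sequences; these baselines quantify that gap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import SimilarityGraph
from .partition import PartitionAssignment, assign_clusters
from .graph import ClusterState
from .records import SequenceRecord

HOBOHM1 = "hobohm1"
HOBOHM2 = "hobohm2"
GREEDY_MIN = "greedy_min"


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of a homology reduction: a kept/removed bipartition of ids."""

    kept: frozenset[str]
    removed: frozenset[str]
    algorithm: str


def hobohm1(records: list[SequenceRecord], sim: SimilarityGraph) -> ReductionResult:
    """Ranked greedy reduction (Hobohm algorithm 1).

    Walk the record list in order (the ranking); keep each sequence not yet
    discarded and discard all its neighbors. Equivalent to the greedy maximal
    independent set in list order — the result depends on the ranking.
    """
    adj = {n: set(sim.graph.neighbors(n)) for n in sim.graph}
    kept: set[str] = set()
    removed: set[str] = set()
    for rec in records:
        if rec.id in removed:
            continue
        kept.add(rec.id)
        removed |= adj[rec.id] - kept
    return ReductionResult(frozenset(kept), frozenset(removed), HOBOHM1)


def hobohm2(sim: SimilarityGraph) -> ReductionResult:
    """Max-degree iterative reduction (Hobohm algorithm 2).

    Repeatedly delete the sequence with the most remaining neighbors
    (ties: lexicographically smallest id) until no neighbor pair remains.
    """
    adj = {n: set(sim.graph.neighbors(n)) for n in sim.graph}
    removed: set[str] = set()
    while True:
        victim = None
        best = 0
        for n in sorted(adj):
            d = len(adj[n])
            if d > best:
                best, victim = d, n
        if victim is None:
            break
        removed.add(victim)
        for nb in adj[victim]:
            adj[nb].discard(victim)
        del adj[victim]
    return ReductionResult(frozenset(adj), frozenset(removed), HOBOHM2)


def greedy_min(sim: SimilarityGraph) -> ReductionResult:
    """Min-degree greedy independent set.

    Repeatedly select the unclassified sequence with the fewest remaining
    neighbors (ties: lexicographically smallest id), keep it, discard its
    neighbors, and recompute. Tends to keep at least as many sequences as
    max-degree removal.
    """
    adj = {n: set(sim.graph.neighbors(n)) for n in sim.graph}
    kept: set[str] = set()
    removed: set[str] = set()
    while adj:
        pick = min(sorted(adj), key=lambda n: len(adj[n]))
        kept.add(pick)
        victims = list(adj[pick])
        del adj[pick]
        for v in victims:
            removed.add(v)
            for nb in adj[v]:
                if nb in adj:
                    adj[nb].discard(v)
            del adj[v]
    return ReductionResult(frozenset(kept), frozenset(removed), GREEDY_MIN)


def fold_reduced_set(
    kept: frozenset[str] | set[str], records: list[SequenceRecord], k: int
) -> PartitionAssignment:
    """Stratified k-fold grouping of a reduced set.

    Kept sequences are treated as singleton clusters (in input order) and
    distributed by the same greedy label-balancing rule used for clusters.
    """
    kept_records = [r for r in records if r.id in kept]
    if not kept_records:
        raise ValueError("kept set is empty")
    if k > len(kept_records):
        raise ValueError(f"k={k} exceeds the {len(kept_records)} kept sequences")
    state = ClusterState(
        clusters=[[r.id] for r in kept_records],
        labels={r.id: r.label for r in kept_records},
    )
    return assign_clusters(state, k)
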