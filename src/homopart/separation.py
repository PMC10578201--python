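"""Iterative move/remove heuristic that eliminates cross-partition neighbors.

After the initial assignment, some neighbor pairs (identity above the
threshold) may still straddle partition boundaries. Each iteration first
relocates sequences that are better connected to a foreign partition than to
their own, then removes the most cross-connected sequences according to a
schedule that starts conservatively (one sequence per iteration) and ramps
up as c·log10(i/100)+1, where c is the number of sequences that still have
cross-partition neighbors and i the iteration counter. The loop ends when no
cross-partition neighbor pair remains.

With binary priorities, removal first runs in a restrained mode that only
draws candidates from the low-priority pool; only if cross-partition
connections persist afterwards does unrestrained removal continue (the
iteration counter carries over). Moves apply to all sequences in both
phases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

from .graph import SimilarityGraph
from .partition import PartitionAssignment


class ConvergenceError(RuntimeError):
    """Separation failed to reach zero cross-partition neighbors in time."""


class FoldLossError(RuntimeError):
    """Separation succeeded only by emptying at least one partition."""


@dataclass
class SeparationConfig:
    allow_moves: bool = True
    priority_aware: bool = False
    max_iterations: int = 10000
    #: downgrade an emptied partition from error to warning
    allow_fold_loss: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    c: int
    moved: int
    removed_ids: tuple[str, ...]


@dataclass
class SeparationTrace:
    records: list[TraceRecord] = field(default_factory=list)

    def total_removed(self) -> int:
        return sum(len(r.removed_ids) for r in self.records)

    def total_moved(self) -> int:
        return sum(r.moved for r in self.records)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration\tc\tmoved\tremoved\n")
            for r in self.records:
                fh.write(f"{r.iteration}\t{r.c}\t{r.moved}\t{len(r.removed_ids)}\n")


def removal_quota(c: int, i: int) -> int:
    """Number of sequences the schedule removes at iteration i.

    Evaluates floor(c·log10(i/100)) + 1, clamped below at 1 (the raw value is
    negative for i < 100, where removal stays maximally conservative). The
    caller additionally never removes more sequences than currently have
    cross-partition neighbors.
    """
    if c < 1:
        raise ValueError("removal_quota requires c >= 1")
    if i < 1:
        raise ValueError("iteration counter starts at 1")
    raw = math.floor(c * math.log10(i / 100)) + 1
    return max(1, raw)


def _adjacency(sim: SimilarityGraph) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in sim.node_order}
    for u, v, _ in sim.edges():
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _cross_count(sid: str, adj, mapping) -> int:
    own = mapping[sid]
    return sum(1 for nb in adj[sid] if mapping[nb] != own)


def _run_phase(
    sim: SimilarityGraph,
    assignment: PartitionAssignment,
    adj: dict[str, set[str]],
    config: SeparationConfig,
    trace: SeparationTrace,
    start_iteration: int,
    candidate_pool: Optional[Callable[[str], bool]] = None,
    close_trace: bool = True,
) -> int:
    """One removal phase; mutates assignment/adj in place.

    ``candidate_pool`` restricts which sequences may be removed (restrained
    mode); the phase ends when no pool member retains a cross-partition
    neighbor. Returns the next iteration counter value.
    """
    mapping = assignment.mapping
    order = [s for s in sim.node_order]
    i = start_iteration
    while True:
        if i > config.max_iterations:
            raise ConvergenceError(
                f"separation did not converge within {config.max_iterations} iterations"
            )
        moved = 0
        if config.allow_moves:
            for sid in order:
                if mapping[sid] is None or not adj[sid]:
                    continue
                own = mapping[sid]
                per_part: dict[int, int] = {}
                for nb in adj[sid]:
                    per_part[mapping[nb]] = per_part.get(mapping[nb], 0) + 1
                within = per_part.get(own, 0)
                foreign = [(p, c) for p, c in per_part.items() if p != own]
                if not foreign:
                    continue
                target, best = min(foreign, key=lambda pc: (-pc[1], pc[0]))
                if best > within:
                    assignment.move(sid, target)
                    moved += 1
        cross = {
            sid: _cross_count(sid, adj, mapping)
            for sid in order
            if mapping[sid] is not None and adj[sid]
        }
        connected = {sid: c for sid, c in cross.items() if c > 0}
        c_total = len(connected)
        if candidate_pool is None:
            pool = connected
        else:
            pool = {sid: c for sid, c in connected.items() if candidate_pool(sid)}
        if not pool:
            # full success, or restrained phase exhausted: close the trace
            if close_trace and trace.records:
                trace.records.append(TraceRecord(i, c_total, moved, ()))
            return i
        quota = removal_quota(len(pool), i)
        victims = sorted(pool, key=lambda sid: (-pool[sid], sid))[:quota]
        for sid in victims:
            assignment.remove(sid)
            for nb in adj[sid]:
                adj[nb].discard(sid)
            adj[sid] = set()
        trace.records.append(TraceRecord(i, c_total, moved, tuple(victims)))
        i += 1


def _check_fold_loss(assignment: PartitionAssignment, allow: bool) -> None:
    empty = [p for p, size in enumerate(assignment.partition_sizes()) if size == 0]
    if empty:
        msg = (
            f"separation emptied partition(s) {empty}: the dataset cannot be "
            f"split into {assignment.k} folds at this threshold"
        )
        if allow:
            warnings.warn(msg)
        else:
            raise FoldLossError(msg)


def separate(
    sim: SimilarityGraph,
    assignment: PartitionAssignment,
    config: SeparationConfig | None = None,
) -> tuple[PartitionAssignment, SeparationTrace]:
    """Move/remove until no neighbor pair crosses partition boundaries.

    Returns a new assignment (removed sequences mapped to None) plus the
    iteration trace. Raises :class:`FoldLossError` if success required
    emptying a partition, :class:`ConvergenceError` on iteration overflow.
    """
    config = config or SeparationConfig()
    result = assignment.copy()
    adj = _adjacency(sim)
    trace = SeparationTrace()
    _run_phase(sim, result, adj, config, trace, start_iteration=1)
    _check_fold_loss(result, config.allow_fold_loss)
    return result, trace


def separate_with_priority(
    sim: SimilarityGraph,
    assignment: PartitionAssignment,
    config: SeparationConfig | None = None,
) -> tuple[PartitionAssignment, SeparationTrace]:
    """Two-phase separation honoring binary priorities.

    Phase 1 removes only low-priority sequences until none of them retains a
    cross-partition neighbor; if cross-partition connections persist among
    the rest, phase 2 continues unrestrained with the iteration counter
    carried over. Moves apply to all sequences throughout.
    """
    config = config or SeparationConfig()
    priorities = sim.priorities()
    result = assignment.copy()
    adj = _adjacency(sim)
    trace = SeparationTrace()
    next_i = _run_phase(
        sim,
        result,
        adj,
        config,
        trace,
        1,
        candidate_pool=lambda s: not priorities[s],
        close_trace=False,
    )
    _run_phase(sim, result, adj, config, trace, next_i)
    _check_fold_loss(result, config.allow_fold_loss)
    return result, trace
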