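"""Independent audit of a partition assignment.

The audit realigns every retained cross-partition pair from scratch — it
never consults the similarity graph used during partitioning — and reports
each sequence's maximum cross-partition identity. A split passes when no
retained sequence has identity above the threshold to any sequence in a
different partition.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import pandas as pd

from .align import AlignmentParams, global_align
from .partition import PartitionAssignment
from .records import SequenceRecord


@dataclass
class SeparationReport:
    """Per-sequence maximum cross-partition identity plus summary fields."""

    max_cross_identity: dict[str, float]
    retention_fraction: float
    partition_label_counts: pd.DataFrame
    threshold: float
    passed: bool

    def to_csv(self, assignment: PartitionAssignment, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "partition", "max_cross_identity"])
            for sid, value in self.max_cross_identity.items():
                writer.writerow([sid, assignment.mapping[sid], f"{value:.6f}"])

    def summary(self) -> dict:
        return {
            "pass": self.passed,
            "retention": self.retention_fraction,
            "threshold": self.threshold,
            "max_cross_identity": max(self.max_cross_identity.values(), default=0.0),
            "partition_label_counts": {
                str(p): {str(l): int(c) for l, c in row.items() if c}
                for p, row in self.partition_label_counts.iterrows()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _label_count_table(
    assignment: PartitionAssignment, records: list[SequenceRecord]
) -> pd.DataFrame:
    labels = sorted({r.label for r in records})
    table = pd.DataFrame(
        0, index=range(assignment.k), columns=labels, dtype=int
    )
    for rec in records:
        p = assignment.mapping[rec.id]
        if p is not None:
            table.loc[p, rec.label] += 1
    return table


def audit_separation(
    records: list[SequenceRecord],
    assignment: PartitionAssignment,
    params: AlignmentParams | None = None,
    threshold: float = 0.5,
) -> SeparationReport:
    """Brute-force separation audit: realign all retained cross-partition pairs.

    Every retained sequence gets its maximum identity to any sequence in a
    different partition (0.0 when no foreign partner exists); the report
    passes iff all values are at or below the threshold. Removed sequences
    are excluded.
    """
    if params is None and records:
        params = AlignmentParams(alphabet=records[0].alphabet)
    retained = [r for r in records if assignment.mapping[r.id] is not None]
    max_cross = {r.id: 0.0 for r in retained}
    for i in range(len(retained)):
        for j in range(i + 1, len(retained)):
            a, b = retained[i], retained[j]
            if assignment.mapping[a.id] == assignment.mapping[b.id]:
                continue
            identity = global_align(a, b, params).identity
            if identity > max_cross[a.id]:
                max_cross[a.id] = identity
            if identity > max_cross[b.id]:
                max_cross[b.id] = identity
    passed = all(v <= threshold for v in max_cross.values())
    return SeparationReport(
        max_cross_identity=max_cross,
        retention_fraction=len(retained) / len(records) if records else 1.0,
        partition_label_counts=_label_count_table(assignment, records),
        threshold=threshold,
        passed=passed,
    )


@dataclass
class BalanceReport:
    """Per-partition per-label counts and per-label worst pairwise deviation."""

    counts: pd.DataFrame
    max_deviation: dict[str, int]


def balance_report(
    assignment: PartitionAssignment, records: list[SequenceRecord]
) -> BalanceReport:
    """Class-balance summary: counts table plus, per label, the maximum
    absolute count difference over all partition pairs."""
    counts = _label_count_table(assignment, records)
    deviation = {
        str(label): int(counts[label].max() - counts[label].min())
        for label in counts.columns
    }
    return BalanceReport(counts=counts, max_deviation=deviation)
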