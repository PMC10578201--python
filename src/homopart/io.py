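"""Reading labeled FASTA and precomputed edge lists; writing partition tables.

Header convention for labeled FASTA: ``>id|key1=value1|key2=value2``.
The key names for the class label and the priority flag are configurable
(defaults ``label`` and ``priority``); priority values are ``1`` (high,
the default when absent) or ``0`` (low).
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .records import (
    DEFAULT_LABEL,
    DatasetError,
    SequenceRecord,
    check_unique_ids,
    detect_alphabet,
)

IDENTITY = "identity"
DISTANCE = "distance"


@dataclass(frozen=True)
class EdgeListEntry:
    """A precomputed pairwise value between two sequences.

    `value` is an identity or a distance in [0, 1] depending on
    `value_kind`; endpoints are stored in canonical (lexicographic) order.
    """

    id_a: str
    id_b: str
    value: float
    value_kind: str

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise DatasetError(f"self-pair edge for id {self.id_a!r}")
        if not 0.0 <= self.value <= 1.0:
            raise DatasetError(
                f"edge value {self.value} for ({self.id_a}, {self.id_b}) "
                "outside [0, 1]"
            )
        if self.value_kind not in (IDENTITY, DISTANCE):
            raise DatasetError(f"unknown value kind {self.value_kind!r}")
        if self.id_a > self.id_b:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_header(header: str, line_no: int) -> tuple[str, dict[str, str]]:
    parts = header.split("|")
    seq_id = parts[0].strip()
    meta: dict[str, str] = {}
    for seg in parts[1:]:
        if "=" not in seg:
            raise DatasetError(
                f"malformed header segment {seg!r} on line {line_no} "
                "(expected key=value)"
            )
        key, _, value = seg.partition("=")
        meta[key.strip()] = value.strip()
    return seq_id, meta


def read_labeled_fasta(
    path,
    label_key: str = "label",
    priority_key: str = "priority",
    alphabet: str = "auto",
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, input order kept.

    Labels and priorities are taken from ``|key=value`` header segments;
    missing keys fall back to the shared default class and high priority.
    With ``alphabet="auto"`` the alphabet is detected from residue
    composition over the whole file.
    """
    raw: list[tuple[str, dict, str, int]] = []
    # Track header line numbers for error messages; SeqIO drops them.
    header_lines: dict[int, int] = {}
    with _open_text(path) as fh:
        entry = -1
        for ln, line in enumerate(fh, start=1):
            if line.startswith(">"):
                entry += 1
                header_lines[entry] = ln
    with _open_text(path) as fh:
        for idx, seq_rec in enumerate(SeqIO.parse(fh, "fasta")):
            line_no = header_lines.get(idx, 0)
            seq_id, meta = _parse_header(seq_rec.description, line_no)
            raw.append((seq_id, meta, str(seq_rec.seq), line_no))
    if alphabet == "auto":
        alphabet = detect_alphabet([seq for _, _, seq, _ in raw])
    records = []
    for seq_id, meta, seq, line_no in raw:
        label = meta.get(label_key, DEFAULT_LABEL)
        prio_raw = meta.get(priority_key, "1")
        if prio_raw not in ("0", "1"):
            raise DatasetError(
                f"priority value {prio_raw!r} for {seq_id!r} on line {line_no} "
                "must be 0 (low) or 1 (high)"
            )
        records.append(
            SequenceRecord(
                id=seq_id,
                sequence=seq,
                label=label,
                priority=prio_raw == "1",
                alphabet=alphabet,
            )
        )
    check_unique_ids(records)
    return records


def read_edge_list(path, value_kind: str = IDENTITY) -> list[EdgeListEntry]:
    """Read a 3-column TSV (id_a, id_b, value) of precomputed pair values.

    Lines starting with ``#`` are comments. Symmetric duplicates must agree
    within 1e-9 and are collapsed to one canonical entry; conflicting
    duplicates are an error.
    """
    seen: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise DatasetError(f"line {ln}: expected 3 tab-separated columns")
            id_a, id_b, raw = cols
            try:
                value = float(raw)
            except ValueError:
                raise DatasetError(f"line {ln}: non-numeric value {raw!r}") from None
            entry = EdgeListEntry(id_a, id_b, value, value_kind)  # validates
            key = (entry.id_a, entry.id_b)
            if key in seen:
                if abs(seen[key] - value) > 1e-9:
                    raise DatasetError(
                        f"line {ln}: conflicting values for pair {key}: "
                        f"{seen[key]} vs {value}"
                    )
                continue
            seen[key] = value
            order.append(key)
    return [EdgeListEntry(a, b, seen[(a, b)], value_kind) for a, b in order]


def write_partition_csv(assignment, records: list[SequenceRecord], path) -> None:
    """Write the per-sequence partition table.

    Columns: ``id,label,priority,cluster,partition,removed``; the partition
    column is empty for removed sequences; rows follow input order.
    """
    mapping = assignment.mapping
    cluster_of = assignment.cluster_of or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "priority", "cluster", "partition", "removed"])
        for rec in records:
            if rec.id not in mapping:
                raise DatasetError(f"id {rec.id!r} missing from assignment")
            part = mapping[rec.id]
            writer.writerow(
                [
                    rec.id,
                    rec.label,
                    1 if rec.priority else 0,
                    cluster_of.get(rec.id, ""),
                    "" if part is None else part,
                    0 if part is not None else 1,
                ]
            )


def read_partition_csv(path) -> dict[str, Optional[int]]:
    """Parse a partition table back into an id -> partition (or None) map."""
    mapping: dict[str, Optional[int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            mapping[row["id"]] = int(row["partition"]) if row["partition"] != "" else None
    return mapping


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records in the labeled-FASTA header convention (60-col wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}|label={rec.label}|priority={1 if rec.priority else 0}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_edge_list(entries: Iterable[EdgeListEntry], path) -> None:
    """Serialize edges as the 3-column TSV accepted by :func:`read_edge_list`."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.id_a}\t{e.id_b}\t{e.value:.10g}\n")
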