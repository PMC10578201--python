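"""Sequence records and alphabet handling.

A dataset is a list of :class:`SequenceRecord`. Each record carries the
metadata the partitioner consumes: a categorical class label (used for
balancing folds) and a binary priority flag (high-priority sequences are
removed last when separation forces removals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

#: Residues accepted per alphabet; the final symbol is the unknown residue.
PROTEIN_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NUCLEOTIDE_RESIDUES = set("ACGTU") | {"N"}

#: Class label used when the input carries none: all sequences share one class.
DEFAULT_LABEL = "default"


class DatasetError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence with its partitioning metadata.

    Parameters
    ----------
    id : str
        Unique, non-empty identifier.
    sequence : str
        Residues (stored upper-case) over `alphabet`, plus the unknown
        symbol (X for protein, N for nucleotide).
    label : str
        Class label used for balancing; defaults to a single shared class.
    priority : bool
        True for high priority (retain preferentially), False for low.
    alphabet : str
        ``"protein"`` or ``"nucleotide"``.
    """

    id: str
    sequence: str
    label: str = DEFAULT_LABEL
    priority: bool = True
    alphabet: str = PROTEIN

    def __post_init__(self) -> None:
        if not self.id:
            raise DatasetError("sequence id must be non-empty")
        if not self.sequence:
            raise DatasetError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        allowed = residues_for(self.alphabet)
        for ch in self.sequence:
            if ch not in allowed:
                raise DatasetError(
                    f"sequence {self.id!r} contains residue {ch!r} outside the "
                    f"{self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def residues_for(alphabet: str) -> set[str]:
    if alphabet == PROTEIN:
        return PROTEIN_RESIDUES
    if alphabet == NUCLEOTIDE:
        return NUCLEOTIDE_RESIDUES
    raise DatasetError(f"unknown alphabet {alphabet!r}")


def detect_alphabet(sequences: list[str]) -> str:
    """Guess the alphabet from residue composition.

    If at least 95% of non-unknown residues fall in {A, C, G, T, U} the
    data is called nucleotide, otherwise protein. Short peptides made of
    ala/cys/gly/thr can in principle be miscalled; pass an explicit
    alphabet to override.
    """
    nuc = total = 0
    for seq in sequences:
        for ch in seq.upper():
            if ch in ("X", "N"):
                continue
            total += 1
            if ch in "ACGTU":
                nuc += 1
    if total == 0:
        return NUCLEOTIDE  # all-unknown input; either call is consistent
    return NUCLEOTIDE if nuc / total >= 0.95 else PROTEIN


def check_unique_ids(records: list[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DatasetError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
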