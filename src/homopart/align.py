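"""Global pairwise alignment and percent identity.

Exact Needleman–Wunsch with affine gap penalties (Gotoh's algorithm),
end gaps penalized. Defaults follow the common EMBOSS conventions:
BLOSUM62 for protein, the EDNAFULL match/mismatch table (+5/−4) for
nucleotides, gap open 10.0 and gap extend 0.5.

Percent identity is the fraction of identical aligned columns; the
denominator is selectable between the full alignment length (including
gap columns, the default here) and the length of the shorter sequence
(the convention of coverage-free local-alignment pipelines, which yields
an identity that is never smaller).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio.Align import substitution_matrices

from ._gotoh import align_pair
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord

ALIGNMENT_LENGTH = "alignment_length"
SHORTER_SEQUENCE = "shorter_sequence"

_UNKNOWN = {PROTEIN: "X", NUCLEOTIDE: "N"}


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs or parameters."""


def _default_matrix(alphabet: str):
    if alphabet == PROTEIN:
        return substitution_matrices.load("BLOSUM62")
    # NUC.4.4 is the EDNAFULL table: match +5, mismatch −4, ambiguity codes scored.
    return substitution_matrices.load("NUC.4.4")


def load_matrix(path):
    """Load a substitution matrix in NCBI/EMBOSS text format."""
    return substitution_matrices.read(str(path))


@dataclass
class AlignmentParams:
    """Scoring parameters for global alignment.

    ``substitution_matrix`` is a Bio.Align substitution matrix (symmetric);
    ``denominator`` selects the identity convention. The unknown residue
    (X/N) uses its matrix entries when present, otherwise scores 0 against
    everything.
    """

    alphabet: str = PROTEIN
    substitution_matrix: object = None
    gap_open: float = 10.0
    gap_extend: float = 0.5
    denominator: str = ALIGNMENT_LENGTH

    # derived encoding caches
    _index: dict = field(default=None, repr=False, compare=False)
    _matrix: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.substitution_matrix is None:
            self.substitution_matrix = _default_matrix(self.alphabet)
        if not (self.gap_open >= self.gap_extend >= 0):
            raise AlignmentError("require gap_open >= gap_extend >= 0")
        if self.denominator not in (ALIGNMENT_LENGTH, SHORTER_SEQUENCE):
            raise AlignmentError(f"unknown denominator {self.denominator!r}")
        letters = list(self.substitution_matrix.alphabet)
        mat = np.asarray(self.substitution_matrix, dtype=np.float64)
        if not np.allclose(mat, mat.T):
            raise AlignmentError("substitution matrix must be symmetric")
        unknown = _UNKNOWN[self.alphabet]
        if unknown not in letters:
            # neutral scoring for the unknown residue when the matrix lacks it
            letters.append(unknown)
            mat = np.pad(mat, ((0, 1), (0, 1)))
        self._index = {ch: i for i, ch in enumerate(letters)}
        self._matrix = np.ascontiguousarray(mat)

    def encode(self, record: SequenceRecord) -> np.ndarray:
        if record.alphabet != self.alphabet:
            raise AlignmentError(
                f"record {record.id!r} has alphabet {record.alphabet}, "
                f"params expect {self.alphabet}"
            )
        try:
            return np.array([self._index[ch] for ch in record.sequence], dtype=np.int64)
        except KeyError as exc:
            raise AlignmentError(
                f"residue {exc.args[0]!r} of {record.id!r} missing from the "
                "substitution matrix"
            ) from None


@dataclass(frozen=True)
class PairwiseResult:
    """Outcome of one global alignment, endpoints in canonical id order."""

    id_a: str
    id_b: str
    score: float
    n_identical: int
    alignment_length: int
    identity: float


def global_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignmentParams | None = None
) -> PairwiseResult:
    """Optimal global affine-gap alignment of two sequences.

    The pair is canonicalized (lexicographically smaller id first) before
    the DP so the result — including the canonical-traceback identity
    count — is identical regardless of argument order.
    """
    if params is None:
        params = AlignmentParams(alphabet=a.alphabet)
    if a.id > b.id:
        a, b = b, a
    ea, eb = params.encode(a), params.encode(b)
    score, n_identical, length = align_pair(
        ea, eb, params._matrix, params.gap_open, params.gap_extend
    )
    if params.denominator == ALIGNMENT_LENGTH:
        denom = length
    else:
        denom = min(len(ea), len(eb))
    identity = n_identical / denom
    return PairwiseResult(
        id_a=a.id,
        id_b=b.id,
        score=float(score),
        n_identical=int(n_identical),
        alignment_length=int(length),
        identity=float(identity),
    )


def all_vs_all(
    records: list[SequenceRecord],
    params: AlignmentParams | None = None,
    triangular: bool = True,
) -> Iterator[PairwiseResult]:
    """Stream pairwise results for every pair of distinct records.

    With ``triangular`` (the default) exactly n(n−1)/2 results are produced,
    one per unordered pair in input-pair order; otherwise the mirror of each
    result is emitted as well (same numbers, endpoints already canonical).
    The computation is per-pair deterministic, so chunked/parallel variants
    merge to the same stream.
    """
    if len(records) < 2:
        raise AlignmentError("all_vs_all needs at least 2 records")
    if params is None:
        params = AlignmentParams(alphabet=records[0].alphabet)
    encoded = [params.encode(r) for r in records]
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            ri, rj = records[i], records[j]
            # canonical order for the DP, mirroring global_align
            if ri.id > rj.id:
                ri, rj = rj, ri
                ea, eb = encoded[j], encoded[i]
            else:
                ea, eb = encoded[i], encoded[j]
            score, n_identical, length = align_pair(
                ea, eb, params._matrix, params.gap_open, params.gap_extend
            )
            if params.denominator == ALIGNMENT_LENGTH:
                denom = length
            else:
                denom = min(len(ea), len(eb))
            result = PairwiseResult(
                ri.id, rj.id, float(score), int(n_identical), int(length),
                n_identical / denom,
            )
            yield result
            if not triangular:
                yield result
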