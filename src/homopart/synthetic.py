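"""Synthetic sequence families with controlled homology structure.

Each family descends from an independent random ancestor; members are copies
of the ancestor with independent per-site substitutions (to a uniformly
chosen different residue). With substitution probability p and alphabet size
q, two members of the same family match at a site with probability
(1−p)² + p²/(q−1), so the expected within-family identity has a closed form
— convenient for oracle checks — while between-family identity stays near
the random-background level. An optional indel rate is available for
stress-testing but breaks the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .graph import SimilarityGraph, build_graph
from .io import EdgeListEntry, IDENTITY
from .records import DatasetError, NUCLEOTIDE, PROTEIN, SequenceRecord

_ALPHABETS = {
    NUCLEOTIDE: "ACGT",
    PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family dataset.

    ``family_size`` is one integer for all families or a per-family list;
    ``labels`` assigns one class label per family (a shorter list is cycled;
    None gives every family the shared default class).
    """

    n_families: int
    family_size: Union[int, Sequence[int]] = 5
    ancestor_length: int = 150
    within_mutation_rate: float = 0.05
    labels: Optional[Sequence[str]] = None
    alphabet: str = NUCLEOTIDE
    seed: int = 0
    indel_rate: float = 0.0

    def sizes(self) -> list[int]:
        if isinstance(self.family_size, int):
            return [self.family_size] * self.n_families
        sizes = list(self.family_size)
        if len(sizes) != self.n_families:
            raise DatasetError("per-family sizes must match n_families")
        return sizes

    def family_labels(self) -> list[str]:
        if self.labels is None:
            return [SequenceRecord.__dataclass_fields__["label"].default] * self.n_families
        return [self.labels[i % len(self.labels)] for i in range(self.n_families)]


def expected_within_identity(rate: float, alphabet_size: int) -> float:
    """Closed-form expected per-site identity of two independently mutated
    copies of one ancestor (substitution-only model)."""
    p, q = rate, alphabet_size
    return (1 - p) ** 2 + p * p / (q - 1)


def _mutate(ancestor: np.ndarray, rate: float, indel_rate: float, rng, q: int):
    seq = ancestor.copy()
    hits = rng.random(len(seq)) < rate
    if hits.any():
        # substitute to a uniformly chosen *different* residue
        shift = rng.integers(1, q, size=int(hits.sum()))
        seq[hits] = (seq[hits] + shift) % q
    if indel_rate > 0:
        out = []
        for site in seq:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(site)
            if r >= 1 - indel_rate / 2:
                out.append(rng.integers(0, q))  # insertion after the site
        seq = np.array(out, dtype=seq.dtype) if out else seq[:1]
    return seq


def generate_families(spec: FamilySpec) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Generate the dataset; returns (records, truth map id -> family index).

    Deterministic given ``spec.seed``; ids encode family and member index
    (``F007_M02``).
    """
    letters = _ALPHABETS[spec.alphabet]
    q = len(letters)
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes()
    fam_labels = spec.family_labels()
    records: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    for fam in range(spec.n_families):
        ancestor = rng.integers(0, q, size=spec.ancestor_length)
        for m in range(sizes[fam]):
            seq = _mutate(ancestor, spec.within_mutation_rate, spec.indel_rate, rng, q)
            sid = f"F{fam:03d}_M{m:02d}"
            records.append(
                SequenceRecord(
                    id=sid,
                    sequence="".join(letters[s] for s in seq),
                    label=fam_labels[fam],
                    priority=True,
                    alphabet=spec.alphabet,
                )
            )
            truth[sid] = fam
    return records, truth


def generate_edge_fixture(
    ids: Union[int, Sequence[str]],
    edge_spec: Sequence[tuple[str, str, float]],
    identity_threshold: float = 0.5,
    labels: Optional[dict[str, str]] = None,
    priorities: Optional[dict[str, bool]] = None,
) -> SimilarityGraph:
    """Construct an exact similarity graph, bypassing alignment.

    ``ids`` is either a node count (ids ``n0..n{k-1}``) or explicit ids;
    ``edge_spec`` lists (id_a, id_b, identity) tuples, all of which must
    strictly exceed the threshold. Node sequences are placeholders — the
    fixture exists to unit-test clustering, partitioning and separation.
    """
    if isinstance(ids, int):
        ids = [f"n{i}" for i in range(ids)]
    labels = labels or {}
    priorities = priorities or {}
    records = [
        SequenceRecord(
            id=i,
            sequence="A",
            label=labels.get(i, "default"),
            priority=priorities.get(i, True),
            alphabet=PROTEIN,
        )
        for i in ids
    ]
    seen: set[tuple[str, str]] = set()
    entries = []
    for a, b, ident in edge_spec:
        if a == b:
            raise DatasetError(f"self edge on {a!r}")
        key = (min(a, b), max(a, b))
        if key in seen:
            raise DatasetError(f"duplicate edge {key}")
        seen.add(key)
        if ident <= identity_threshold:
            raise DatasetError(
                f"fixture edge {key} identity {ident} does not exceed the "
                f"threshold {identity_threshold}"
            )
        entries.append(EdgeListEntry(a, b, ident, IDENTITY))
    return build_graph(entries, records, identity_threshold)
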