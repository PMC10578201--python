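"""Shared fixtures: small hand-built graphs and the large synthetic dataset."""

from __future__ import annotations

import pytest

import homopart as hp


@pytest.fixture
def protein_records():
    return [
        hp.SequenceRecord("s1", "ACDEFGHIK", label="pos"),
        hp.SequenceRecord("s2", "ACDEFGHIR", label="neg"),
        hp.SequenceRecord("s3", "WWWWYYYY", label="pos", priority=False),
    ]


@pytest.fixture
def two_cliques_graph():
    """Two 3-cliques at identity 0.9, no cross edges."""
    edges = [
        ("a", "b", 0.9), ("a", "c", 0.9), ("b", "c", 0.9),
        ("d", "e", 0.9), ("d", "f", 0.9), ("e", "f", 0.9),
    ]
    return hp.generate_edge_fixture(["a", "b", "c", "d", "e", "f"], edges, 0.5)


@pytest.fixture(scope="session")
def family_dataset():
    """The 40-family x 5-member nucleotide dataset (length 150, rate 0.05)."""
    spec = hp.FamilySpec(
        n_families=40,
        family_size=5,
        ancestor_length=150,
        within_mutation_rate=0.05,
        alphabet="nucleotide",
        seed=0,
    )
    records, truth = hp.generate_families(spec)
    return records, truth


@pytest.fixture(scope="session")
def family_params():
    return hp.AlignmentParams(alphabet="nucleotide")


@pytest.fixture(scope="session")
def family_graph(family_dataset, family_params):
    """Similarity graph of the family dataset at identity threshold 0.5."""
    records, _ = family_dataset
    results = hp.all_vs_all(records, family_params)
    return hp.build_graph(results, records, 0.5)
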