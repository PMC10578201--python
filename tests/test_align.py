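"""Global aligner: worked examples, invariants, and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homopart as hp
from homopart.align import ALIGNMENT_LENGTH, SHORTER_SEQUENCE, AlignmentError, load_matrix
from homopart.records import SequenceRecord

from oracles import best_alignment_by_enumeration

NT = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"


def nt_rec(sid, seq):
    return SequenceRecord(sid, seq, alphabet="nucleotide")


def nt_params(**kw):
    return hp.AlignmentParams(alphabet="nucleotide", **kw)


def ednafull_score(x, y):
    return 5.0 if x == y else -4.0


class TestGlobalAlign:
    def test_identical_sequences(self):
        a = SequenceRecord("a", "ACDEFG")
        b = SequenceRecord("b", "ACDEFG")
        for denom in (ALIGNMENT_LENGTH, SHORTER_SEQUENCE):
            r = hp.global_align(a, b, hp.AlignmentParams(denominator=denom))
            assert r.identity == 1.0
            assert r.n_identical == 6
            assert r.alignment_length == 6

    def test_single_mismatch_gapless_optimum(self):
        r = hp.global_align(nt_rec("a", "ACGT"), nt_rec("b", "ACGA"), nt_params())
        assert (r.n_identical, r.alignment_length, r.identity) == (3, 4, 0.75)

    def test_denominator_choice_on_nested_pair(self):
        a, b = nt_rec("a", "ACGT"), nt_rec("b", "ACGTACGT")
        short = hp.global_align(a, b, nt_params(denominator=SHORTER_SEQUENCE))
        full = hp.global_align(a, b, nt_params(denominator=ALIGNMENT_LENGTH))
        assert short.identity == 1.0
        assert full.identity == 0.5
        assert full.n_identical == 4 and full.alignment_length == 8

    def test_symmetry_under_argument_order(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = nt_rec("a", "".join(rng.choice(list(NT), 30)))
            b = nt_rec("b", "".join(rng.choice(list(NT), 25)))
            assert hp.global_align(a, b, nt_params()) == hp.global_align(b, a, nt_params())

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(AlignmentError, match="alphabet"):
            hp.global_align(SequenceRecord("a", "ACGT", alphabet="protein"),
                            nt_rec("b", "ACGT"), nt_params())

    def test_mutation_without_indels_counts_matches(self):
        # duplicate a sequence, substitute m of L positions: gapless optimum
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list(NT), 8))
        for m in range(3):
            mutated = list(base)
            for pos in range(m):
                mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            r = hp.global_align(nt_rec("a", base), nt_rec("b", "".join(mutated)), nt_params())
            assert r.n_identical == len(base) - m

    @given(
        st.text(NT, min_size=1, max_size=7),
        st.text(NT, min_size=1, max_size=7),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_enumeration(self, sa, sb):
        """Score equals the max over ALL global alignments; the canonical
        traceback's identity count belongs to a co-optimal alignment."""
        r = hp.global_align(nt_rec("a", sa), nt_rec("b", sb), nt_params())
        best, id_counts, lengths = best_alignment_by_enumeration(
            sa, sb, ednafull_score, 10.0, 0.5
        )
        assert r.score == pytest.approx(best)
        assert r.n_identical in id_counts
        assert r.alignment_length in lengths[r.n_identical]
        assert r.n_identical <= min(len(sa), len(sb))
        assert r.alignment_length >= max(len(sa), len(sb))

    @given(st.text(AA, min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_self_identity_is_one(self, seq):
        a, b = SequenceRecord("a", seq), SequenceRecord("b", seq)
        for denom in (ALIGNMENT_LENGTH, SHORTER_SEQUENCE):
            assert hp.global_align(a, b, hp.AlignmentParams(denominator=denom)).identity == 1.0

    def test_matches_biopython_on_random_proteins(self):
        """Second, independent alignment engine agrees on score and identity."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.5
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(11)
        params = hp.AlignmentParams()
        for _ in range(10):
            sa = "".join(rng.choice(list(AA), 40))
            sb = "".join(rng.choice(list(AA), 35))
            mine = hp.global_align(SequenceRecord("a", sa), SequenceRecord("b", sb), params)
            theirs = aligner.align(sa, sb)
            assert mine.score == pytest.approx(theirs.score)
            cols = list(zip(str(theirs[0][0]), str(theirs[0][1])))
            n_id = sum(1 for x, y in cols if x == y and x != "-")
            # co-optimal paths may differ; identical-column count must match
            # when biopython's first path has the same length
            if len(cols) == mine.alignment_length:
                assert mine.n_identical == n_id


class TestAllVsAll:
    def test_triangular_pair_count(self):
        recs = [nt_rec(f"s{i}", "ACGTACGT") for i in range(4)]
        assert len(list(hp.all_vs_all(recs, nt_params()))) == 6

    def test_mirrors_global_align(self):
        rng = np.random.default_rng(9)
        recs = [nt_rec(f"s{i}", "".join(rng.choice(list(NT), 20))) for i in range(5)]
        params = nt_params()
        for r in hp.all_vs_all(recs, params):
            ra = next(x for x in recs if x.id == r.id_a)
            rb = next(x for x in recs if x.id == r.id_b)
            assert hp.global_align(ra, rb, params) == r

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(AlignmentError):
            list(hp.all_vs_all([nt_rec("a", "ACGT")], nt_params()))

    def test_non_triangular_doubles_stream(self):
        recs = [nt_rec(f"s{i}", "ACGT") for i in range(3)]
        assert len(list(hp.all_vs_all(recs, nt_params(), triangular=False))) == 6


class TestParams:
    def test_invalid_gap_ordering(self):
        with pytest.raises(AlignmentError):
            hp.AlignmentParams(gap_open=0.2, gap_extend=0.5)

    def test_emboss_matrix_file_loadable(self, tmp_path):
        text = (
            "   A  C  G  T\n"
            "A  5 -4 -4 -4\n"
            "C -4  5 -4 -4\n"
            "G -4 -4  5 -4\n"
            "T -4 -4 -4  5\n"
        )
        p = tmp_path / "mat.txt"
        p.write_text(text)
        mat = load_matrix(p)
        params = hp.AlignmentParams(alphabet="nucleotide", substitution_matrix=mat)
        r = hp.global_align(nt_rec("a", "ACGT"), nt_rec("b", "ACGA"), params)
        assert r.identity == 0.75
        # N absent from the custom matrix: neutral zero scoring kicks in
        r2 = hp.global_align(nt_rec("a", "ACGN"), nt_rec("b", "ACGN"), params)
        assert r2.score == pytest.approx(15.0)
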