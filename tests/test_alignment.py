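import random

import pytest
from hypothesis import given, settings, strategies as st
from Bio import Align as bio_align
from Bio.Align import substitution_matrices

from interonet.alignment import (
    AlignmentError,
    AlignmentParams,
    global_align,
    load_matrix,
    similarity,
    simple_matrix,
)
from interonet.seqio import ProteinRecord

from conftest import DNAISH, random_seq
from oracles import (
    brute_force_best_score,
    linear_nw_score,
    recursive_affine_score,
    score_alignment,
)


def _sub(matrix):
    return lambda x, y: float(matrix[x, y])


class TestWorkedExamples:
    def test_self_alignment_scores_the_diagonal(self):
        blosum = load_matrix("BLOSUM62")
        res = global_align("MKV", "MKV")
        assert res.score == float(
            blosum["M", "M"] + blosum["K", "K"] + blosum["V", "V"]
        )
        assert res.identity_pct == 100.0
        assert res.similarity_pct == 100.0

    def test_linear_gap_example_matches_enumeration(self):
        """AAG vs AG at match +1 / mismatch -1 / linear gap -2."""
        m = simple_matrix(1, -1, "ACGT")
        params = AlignmentParams(matrix=m, gap_open=-2, gap_extend=-2)
        res = global_align("AAG", "AG", params)
        best = brute_force_best_score("AAG", "AG", _sub(m), -2, -2)
        assert res.score == best == 0.0
        # the returned alignment is itself optimal and deterministic
        assert score_alignment(res.aligned_a, res.aligned_b, _sub(m), -2, -2) == 0.0
        assert (res.aligned_a, res.aligned_b) == ("AAG", "-AG")

    def test_three_of_four_identical_columns(self):
        a = ProteinRecord("sp1", "A", "MKVL")
        b = ProteinRecord("sp2", "B", "MKIL")
        assert similarity(a, b, mode="identity") == 75.0

    def test_identity_statistic_is_zero_for_disjoint_residues(self):
        m = simple_matrix(1, -1, "ACGT")
        params = AlignmentParams(matrix=m, gap_open=-1, gap_extend=-1)
        res = global_align("AAAA", "GGGG", params)
        assert res.identity_pct == 0.0


class TestParams:
    @pytest.mark.parametrize("go,ge", [(-1, -2), (1, 1), (-1, 0), (0, 0)])
    def test_invalid_gap_penalties_rejected(self, go, ge):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=go, gap_extend=ge)

    def test_unknown_matrix_name(self):
        with pytest.raises(AlignmentError, match="NOTAMATRIX"):
            AlignmentParams(matrix="NOTAMATRIX").resolve_matrix()

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(AlignmentError, match="'J'"):
            global_align("MJV", "MKV")

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            global_align("", "MKV")

    def test_custom_matrix_file(self, tmp_path):
        path = tmp_path / "mat.txt"
        path.write_text("   A  C\nA  2 -1\nC -1  2\n")
        params = AlignmentParams(matrix=str(path), gap_open=-2, gap_extend=-1)
        assert global_align("AC", "AC", params).score == 4.0


class TestAgainstOracles:
    def test_exhaustive_enumeration_short_sequences(self, unit_params):
        rng = random.Random(42)
        m = unit_params.resolve_matrix()
        for _ in range(60):
            a = random_seq(rng, 5)
            b = random_seq(rng, 5)
            expected = brute_force_best_score(
                a, b, _sub(m), unit_params.gap_open, unit_params.gap_extend
            )
            assert global_align(a, b, unit_params).score == expected

    def test_linear_gap_limit_equals_classical_dp(self, unit_params):
        rng = random.Random(7)
        m = unit_params.resolve_matrix()
        params = AlignmentParams(matrix=m, gap_open=-2, gap_extend=-2)
        for _ in range(100):
            a = random_seq(rng, 20)
            b = random_seq(rng, 20)
            assert global_align(a, b, params).score == linear_nw_score(
                a, b, _sub(m), -2
            )

    def test_scores_match_biopython_on_protein_pairs(self):
        """Cross-check against an independent affine-gap implementation."""
        aligner = bio_align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        rng = random.Random(3)
        for _ in range(50):
            a = random_seq(rng, 40, "ACDEFGHIKLMNPQRSTVWY", min_len=5)
            b = random_seq(rng, 40, "ACDEFGHIKLMNPQRSTVWY", min_len=5)
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    a=st.text(alphabet=DNAISH, min_size=1, max_size=14),
    b=st.text(alphabet=DNAISH, min_size=1, max_size=14),
)
def test_alignment_invariants(a, b, unit_params):
    res = global_align(a, b, unit_params)
    res_rev = global_align(b, a, unit_params)
    # score symmetry
    assert res.score == res_rev.score
    # equal-length, no gap-gap column
    assert len(res.aligned_a) == len(res.aligned_b)
    assert all(
        not (ca == "-" and cb == "-")
        for ca, cb in zip(res.aligned_a, res.aligned_b)
    )
    # removing gaps recovers the inputs
    assert res.aligned_a.replace("-", "") == a
    assert res.aligned_b.replace("-", "") == b
    # length bounds
    assert max(len(a), len(b)) <= len(res.aligned_a) <= len(a) + len(b)
    # percentage ordering
    assert 0.0 <= res.identity_pct <= res.similarity_pct <= 100.0
    # independent recursive oracle agrees on the score
    m = unit_params.resolve_matrix()
    assert res.score == recursive_affine_score(
        a, b, _sub(m), unit_params.gap_open, unit_params.gap_extend
    )
    # the reported alignment achieves the reported score
    assert res.score == score_alignment(
        res.aligned_a, res.aligned_b, _sub(m),
        unit_params.gap_open, unit_params.gap_extend,
    )


def test_similarity_mode_and_symmetry():
    a = ProteinRecord("sp1", "A", "MKVLW")
    b = ProteinRecord("sp2", "B", "MRILW")
    for mode in ("identity", "similarity"):
        assert similarity(a, b, mode=mode) == similarity(b, a, mode=mode)
    # K/R and V/I score positively under BLOSUM62, so similarity > identity
    assert similarity(a, b, mode="similarity") > similarity(a, b, mode="identity")
    with pytest.raises(ValueError):
        similarity(a, b, mode="blah")
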