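"""k-word distance, NW alignment/distance conventions, sparse all-pairs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_align_score, oracle_align_score
from tsclust import (AlignmentParams, KmerParams, ParameterError, Read,
                     dereplicate, kmer_distance, nw_align, nw_distance,
                     nw_pair_distance, sparse_all_pairs)
from tsclust.distances import SparseDistanceSet

ILL = AlignmentParams()
P454 = AlignmentParams(platform="454")

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestKmerDistance:
    def test_identity_is_zero(self):
        assert kmer_distance("ACGTACGT", "ACGTACGT", 6) == 0.0

    def test_disjoint_words(self):
        assert kmer_distance("AAAAAA", "CCCCCC", 2) == 1.0

    def test_hand_counted_two_mers(self):
        # shared 2-mers of ACGTA/ACGTT: {AC, CG, GT}; denominator 5-2+1
        assert kmer_distance("ACGTA", "ACGTT", 2) == pytest.approx(1 - 3 / 4)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            kmer_distance("ACG", "ACGTACGT", 6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(s1=st.text(alphabet="ACGT", min_size=3, max_size=12),
           s2=st.text(alphabet="ACGT", min_size=3, max_size=12))
    def test_symmetric_and_bounded(self, s1, s2):
        d = kmer_distance(s1, s2, 3)
        assert d == kmer_distance(s2, s1, 3)
        assert 0.0 <= d <= 1.0


class TestNwAlign:
    def test_identity(self):
        a1, a2, score = nw_align("ACGT", "ACGT", ILL)
        assert (a1, a2, score) == ("ACGT", "ACGT", 4.0)

    def test_internal_deletion_scores_like_oracle(self):
        # frozen from the exhaustive-enumeration oracle: the 1-shift
        # alignment (one end-gap column each side at -1) scores 0
        a1, a2, score = nw_align("ACGTACGT", "ACGACGT", ILL)
        assert score == oracle_align_score("ACGTACGT", "ACGACGT") == 0.0

    def test_contained_sequence_aligns_inside(self):
        a1, a2, score = nw_align("AAAA", "TTAAAATT", ILL)
        assert a2 == "TTAAAATT"
        assert a1.strip("-") == "AAAA"  # no internal gaps: sits inside
        assert score == oracle_align_score("AAAA", "TTAAAATT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            nw_align("", "ACGT", ILL)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(s1=dna, s2=dna,
           setting=st.sampled_from([(True, "illumina"), (False, "illumina"),
                                    (True, "454"), (False, "454")]))
    def test_score_matches_memoized_oracle(self, s1, s2, setting):
        x, platform = setting
        p = AlignmentParams(exclude_end_gaps=x, platform=platform)
        _, _, score = nw_align(s1, s2, p)
        assert score == pytest.approx(oracle_align_score(s1, s2, platform=platform))

    @pytest.mark.parametrize("s1,s2", [("ACA", "CAC"), ("AACC", "CA"),
                                       ("ACGT", "TGCA"), ("AA", "AAAA")])
    def test_enumerator_agrees_with_memoized_oracle(self, s1, s2):
        for platform in ("illumina", "454"):
            assert enumerate_align_score(s1, s2, platform=platform) == \
                pytest.approx(oracle_align_score(s1, s2, platform=platform))


class TestNwDistance:
    def test_single_substitution(self):
        assert nw_distance("ACGTACGTAC", "ACGTTCGTAC", ILL) == pytest.approx(0.1)

    def test_gap_run_counting(self):
        # one 4-column gap run: 4 differences on illumina, 1 indel on 454
        assert nw_distance("ACGT----AC", "ACGTTTTTAC", ILL) == pytest.approx(0.4)
        assert nw_distance("ACGT----AC", "ACGTTTTTAC", P454) == pytest.approx(0.1)

    def test_end_gaps_trimmed(self):
        assert nw_distance("--ACGT", "TTACGT", ILL) == 0.0

    def test_end_gaps_counted_without_x(self):
        p = AlignmentParams(exclude_end_gaps=False)
        assert nw_distance("--ACGT", "TTACGT", p) == pytest.approx(2 / 6)

    def test_all_gap_column_is_internal_error(self):
        with pytest.raises(AssertionError):
            nw_distance("A-C", "A-C", ILL)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            nw_distance("ACGT", "ACG", ILL)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(s1=dna, s2=dna)
    def test_454_never_exceeds_illumina_on_same_alignment(self, s1, s2):
        a1, a2, _ = nw_align(s1, s2, ILL)
        assert nw_distance(a1, a2, P454) <= nw_distance(a1, a2, ILL) + 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(s1=dna, s2=dna)
    def test_pair_distance_consistent_with_align_plus_count(self, s1, s2):
        for p in (ILL, P454):
            a1, a2, _ = nw_align(s1, s2, p)
            assert nw_pair_distance(s1, s2, p) == pytest.approx(nw_distance(a1, a2, p))

    def test_gapfree_pairs_equal_hamming_fraction(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=100))
        for nsub in (1, 2, 3):
            pos = rng.choice(100, size=nsub, replace=False)
            mutated = list(base)
            for p in pos:
                mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
            assert nw_pair_distance(base, "".join(mutated), ILL) == pytest.approx(nsub / 100)


class TestSparseAllPairs:
    def test_single_substitution_pair(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=100))
        other = "C" + base[1:] if base[0] != "C" else "G" + base[1:]
        tags = dereplicate([Read("a", base), Read("b", base), Read("c", other)])
        dset = sparse_all_pairs(tags, KmerParams(), ILL, cap=0.10)
        assert len(dset) == 1
        assert dset.d[0] == pytest.approx(0.01)
        assert dset.n_alignments == 1

    def test_prescreen_rejects_disjoint_kmers(self):
        tags = [Read("a", "A" * 40), Read("b", "C" * 40)]
        dset = sparse_all_pairs(dereplicate(tags), KmerParams(), ILL)
        assert len(dset) == 0
        assert dset.n_alignments == 0

    def test_text_roundtrip(self, tmp_path, rng):
        base = "".join(rng.choice(list("ACGT"), size=80))
        variants = [base] + ["".join("ACGT"[(("ACGT".index(c)) + 1) % 4]
                                     if i == k else c for i, c in enumerate(base))
                             for k in (0, 5, 11)]
        tags = dereplicate([Read(f"r{i}", s) for i, s in enumerate(variants)])
        dset = sparse_all_pairs(tags)
        path = tmp_path / "dist.txt"
        dset.to_text(path)
        back = SparseDistanceSet.from_text(path, cap=dset.cap, n_tags=dset.n_tags)
        assert list(back.i) == list(dset.i)
        assert list(back.j) == list(dset.j)
        np.testing.assert_allclose(back.d, dset.d, atol=1e-6)
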