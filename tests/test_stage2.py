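"""Greedy rare-tag assignment: the alignment-free shortcut, the batched
k-word-ordered NW search, and the five assignment/merge cases."""

import numpy as np
import pytest

from tsclust import (AlignmentParams, KmerParams, SearchParams, Tag,
                     dereplicate, nw_pair_distance, precluster2_shortcut,
                     run_stage2, split_by_cutoff)
from tsclust.derep import Read
from tsclust.stage1 import OTU
from tsclust.stage2 import Stage2Stats, build_index, greedy_assign

AP = AlignmentParams()
KP = KmerParams()
SP = SearchParams()

ROT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _mutate(base, positions, source=None):
    """Substitute at positions; with ``source``, copy its characters."""
    out = list(base)
    for p in positions:
        out[p] = source[p] if source is not None else ROT[out[p]]
    return "".join(out)


def _tag(seq, abundance, rank):
    return Tag(seq=seq, abundance=abundance, rank=rank,
               exemplar_id=f"x{rank}", read_ids=tuple(f"x{rank}_{i}" for i in range(abundance)))


def _haotus(seq_abund):
    otus = []
    for i, (seq, ab) in enumerate(seq_abund):
        otus.append(OTU(id=i, kind="HAOTU", members=[(_tag(seq, ab, i), "direct")]))
    return otus


@pytest.fixture()
def base(rng):
    return "".join(rng.choice(list("ACGT"), size=100))


class TestShortcut:
    def test_identical_tag_hits_its_otu(self, base):
        index = build_index(_haotus([(base, 50)]), KP)
        assert precluster2_shortcut(_tag(base, 1, 9), index, 0.03) == 0

    def test_two_substitutions_within_threshold(self, base):
        index = build_index(_haotus([(base, 50)]), KP)
        rare = _tag(_mutate(base, [10, 50]), 1, 9)
        assert precluster2_shortcut(rare, index, 0.03) == 0

    def test_threshold_is_strict(self, base):
        index = build_index(_haotus([(base, 50)]), KP)
        rare = _tag(_mutate(base, [10, 50, 90]), 1, 9)  # exactly 0.03
        assert precluster2_shortcut(rare, index, 0.03) is None

    def test_internal_indel_frameshift_misses(self, base):
        # a single internal deletion shifts the tail: the gap-free
        # distance explodes even though the NW distance stays tiny
        shifted = base[:20] + base[21:] + "A"
        index = build_index(_haotus([(base, 50)]), KP)
        assert nw_pair_distance(base, shifted, AP) <= 0.03
        assert precluster2_shortcut(_tag(shifted, 1, 9), index, 0.03) is None

    def test_gapfree_distance_upper_bounds_nw(self, rng):
        # soundness: any shortcut hit would also satisfy the NW threshold
        from tsclust.distances import encode
        from tsclust._kernels import direct_distance
        for _ in range(50):
            s = "".join(rng.choice(list("ACGT"), size=80))
            nsub = int(rng.integers(0, 6))
            t = _mutate(s, rng.choice(80, size=nsub, replace=False)) if nsub else s
            assert nw_pair_distance(s, t, AP) <= direct_distance(
                encode(s), encode(t)) + 1e-12


class TestGreedyCases:
    def test_case1_no_hit_creates_laotu(self, base, rng):
        index = build_index(_haotus([(base, 50)]), KP)
        far = "".join(rng.choice(list("ACGT"), size=100))
        stats = Stage2Stats()
        case = greedy_assign(_tag(far, 1, 9), index, SP, AP, KP, stats)
        assert case == 1
        assert sum(1 for o in index.otus.values() if o.kind == "LAOTU") == 1

    def test_case2_single_otu_hit_joins_it(self, base):
        index = build_index(_haotus([(base, 50)]), KP)
        rare = _tag(_mutate(base, [10, 50, 90]), 1, 9)  # NW 0.03 <= d, non-strict
        case = greedy_assign(rare, index, SP, AP, KP, Stage2Stats())
        assert case == 2
        assert len(index.otus) == 1
        assert rare.seq in {t.seq for t in index.otus[0].tags}

    def test_case3_most_abundant_haotu_wins_without_merging(self, base):
        A = base
        B = _mutate(base, range(6))
        R = _mutate(base, range(3), source=B)  # 3 subs to each side
        index = build_index(_haotus([(A, 50), (B, 80)]), KP)
        case = greedy_assign(_tag(R, 1, 9), index, SP, AP, KP, Stage2Stats())
        assert case == 3
        assert len(index.otus) == 2  # HAOTUs never merge
        assert R in {t.seq for t in index.otus[1].tags}  # B's OTU (abundance 80)

    def test_case4_merges_laotus(self, base, rng):
        A = "".join(rng.choice(list("ACGT"), size=100))
        L1 = _mutate(base, range(6))
        L2 = _mutate(base, range(3), source=L1)
        L2 = _mutate(L2, [6, 7, 8])
        R = _mutate(base, range(6), source=L1)
        R = _mutate(R, [6, 7, 8], source=L2)
        index = build_index(_haotus([(A, 50)]), KP)
        sp = SearchParams(shortcut=False)
        for seq in (L1, L2):
            assert greedy_assign(_tag(seq, 1, 8), index, sp, AP, KP, Stage2Stats()) == 1
        case = greedy_assign(_tag(R, 1, 9), index, sp, AP, KP, Stage2Stats())
        assert case == 4
        kinds = sorted(o.kind for o in index.otus.values())
        assert kinds == ["HAOTU", "LAOTU"]  # two LAOTUs merged into one
        laotu = next(o for o in index.otus.values() if o.kind == "LAOTU")
        assert {L1, L2, R} <= {t.seq for t in laotu.tags}

    def test_case5_folds_laotus_into_best_haotu(self, base):
        A = base
        L1 = _mutate(base, range(6))
        L2 = _mutate(base, range(3), source=L1)
        L2 = _mutate(L2, [6, 7, 8])
        R = _mutate(base, range(3), source=L1)  # 3 subs: within 0.03 of all
        index = build_index(_haotus([(A, 50)]), KP)
        sp = SearchParams(shortcut=False)
        for seq in (L1, L2):
            assert greedy_assign(_tag(seq, 1, 8), index, sp, AP, KP, Stage2Stats()) == 1
        n_before = len(index.otus)
        case = greedy_assign(_tag(R, 1, 9), index, sp, AP, KP, Stage2Stats())
        assert case == 5
        assert len(index.otus) == n_before - 2
        (otu,) = index.otus.values()
        assert otu.kind == "HAOTU"
        assert {A, L1, L2, R} == {t.seq for t in otu.tags}


class TestBatchedSearch:
    def _fixture(self, base):
        # k-word order C1 < C2 < C3 while NW hits are C1 and C3 only:
        # clustered substitutions destroy few words, spread ones many
        C1 = _mutate(base, [40])                      # NW 0.01, kd small
        C2 = _mutate(base, [50, 51, 52, 53])          # NW 0.04 (no hit), kd mid
        C3 = _mutate(base, [10, 20, 30])              # NW 0.03 (hit), kd large
        return base, C1, C2, C3

    def test_stops_after_first_empty_batch(self, base):
        Q, C1, C2, C3 = self._fixture(base)
        index = build_index(_haotus([(C1, 50), (C2, 60), (C3, 80)]), KP)
        stats = Stage2Stats()
        sp = SearchParams(batch=1, shortcut=False)
        case = greedy_assign(_tag(Q, 1, 9), index, sp, AP, KP, stats)
        # batch1 = {C1}: hit; batch2 = {C2}: empty -> stop; C3 never aligned
        assert stats.nw_alignments == 2
        assert case == 2
        assert Q in {t.seq for t in index.otus[0].tags}

    def test_larger_batch_finds_both_hits(self, base):
        Q, C1, C2, C3 = self._fixture(base)
        index = build_index(_haotus([(C1, 50), (C2, 60), (C3, 80)]), KP)
        stats = Stage2Stats()
        sp = SearchParams(batch=3, shortcut=False)
        case = greedy_assign(_tag(Q, 1, 9), index, sp, AP, KP, stats)
        assert stats.nw_alignments == 3
        assert case == 3  # hits in two HAOTUs; joins C3's (abundance 80)
        assert Q in {t.seq for t in index.otus[2].tags}


class TestRunStage2:
    def test_empty_rare_returns_haotus_unchanged(self, base):
        haotus = _haotus([(base, 5)])
        split = split_by_cutoff(dereplicate([Read(f"r{i}", base) for i in range(5)]), 1)
        otus, stats, _ = run_stage2(split, haotus, SP, AP, KP)
        assert [o.id for o in otus] == [0]
        assert stats.nw_alignments == 0

    def test_distant_singleton_becomes_laotu(self, base, rng):
        far = "".join(rng.choice(list("ACGT"), size=100))
        assert nw_pair_distance(base, far, AP) > 0.03
        reads = [Read(f"r{i}", base) for i in range(5)] + [Read("r9", far)]
        tags = dereplicate(reads)
        split = split_by_cutoff(tags, 2)
        haotus = _haotus([(base, 5)])
        otus, _stats, _ = run_stage2(split, haotus, SP, AP, KP)
        assert len(otus) == 2
        assert sorted(o.kind for o in otus) == ["HAOTU", "LAOTU"]

    def test_partition_and_haotu_count_preserved(self, mock_small):
        from tsclust import RunConfig, run_tsc, validate_partition
        from tsclust.params import ClusterParams
        _cfg, reads, _ = mock_small
        for cutoff in (2, 4):
            res = run_tsc(reads, RunConfig(cutoff=cutoff))
            validate_partition(res)
            # stage 2 never merges or deletes HAOTUs
            assert res.n_haotus == sum(1 for o in res.otus if o.kind == "HAOTU")
            placed = [t.rank for o in res.otus for t in o.tags]
            assert sorted(placed) == list(range(len(placed)))
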