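"""Stage 2: greedy assignment of rare tags into existing OTUs.

Each rare tag is tried first against OTU representatives with an
alignment-free, position-wise comparison (precluster 2); if that fails,
placed tags are ranked by k-word distance and NW distances are evaluated
in batches until a batch yields no hit.  The accumulated hit set then
decides among five cases: new LAOTU, join the single hit OTU, join the
HAOTU of the most abundant hit tag (HAOTUs are never merged), merge hit
LAOTUs, or fold hit LAOTUs into the best HAOTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .derep import Tag, TagSplit
from .distances import encode, _gap_scores
from .params import AlignmentParams, KmerParams, SearchParams
from .stage1 import OTU, PreclusterResult


class _KmerStore:
    """Contiguous, growable store of per-tag k-word arrays for the kernel."""

    def __init__(self) -> None:
        self._data = np.empty(4096, np.int64)
        self._off = [0]
        self._lens: list[int] = []

    def append(self, karr: np.ndarray, seqlen: int) -> None:
        end = self._off[-1]
        need = end + karr.shape[0]
        if need > self._data.shape[0]:
            grown = np.empty(max(need, 2 * self._data.shape[0]), np.int64)
            grown[:end] = self._data[:end]
            self._data = grown
        self._data[end:need] = karr
        self._off.append(need)
        self._lens.append(seqlen)

    @property
    def n(self) -> int:
        return len(self._lens)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self._data, np.asarray(self._off, np.int64),
                np.asarray(self._lens, np.int64))


@dataclass
class Stage2Stats:
    shortcut_placements: int = 0
    nw_alignments: int = 0
    case_counts: dict[int, int] = field(default_factory=lambda: {c: 0 for c in range(1, 6)})
    trace: list[tuple[str, int, int | None]] = field(default_factory=list)


class OtuIndex:
    """Live OTU collection plus the searchable placed-tag side structures.

    ``rank_targets`` selects whether the k-word ranking runs against all
    placed tags (default; matches the memory profile of the original
    method) or only current OTU representatives.
    """

    def __init__(self, kp: KmerParams, rank_targets: str = "all") -> None:
        if rank_targets not in ("all", "representatives"):
            raise ValueError("rank_targets must be 'all' or 'representatives'")
        self.kp = kp
        self.rank_targets = rank_targets
        self.otus: dict[int, OTU] = {}
        self.next_id = 0
        # per placed tag, in placement order:
        self.tags: list[Tag] = []
        self.codes: list[np.ndarray] = []
        self.weights: list[int] = []
        self.otu_of: list[int] = []
        self._kstore = _KmerStore()
        # otu id -> (rep weight, rep codes); insertion order = creation order
        self.reps: dict[int, tuple[int, np.ndarray, Tag]] = {}

    # -- construction ---------------------------------------------------
    def place(self, tag: Tag, otu_id: int, via: str, weight: int | None = None) -> None:
        w = tag.abundance if weight is None else weight
        codes = encode(tag.seq)
        self.tags.append(tag)
        self.codes.append(codes)
        self.weights.append(w)
        self.otu_of.append(otu_id)
        self._kstore.append(_kernels.encode_kmers(codes, self.kp.k), len(tag.seq))
        self.otus[otu_id].members.append((tag, via))
        self._update_rep(otu_id, w, codes, tag)

    def _update_rep(self, otu_id: int, w: int, codes: np.ndarray, tag: Tag) -> None:
        rep = self.reps.get(otu_id)
        if rep is None or w > rep[0] or (w == rep[0] and tag.seq < rep[2].seq):
            self.reps[otu_id] = (w, codes, tag)

    def new_otu(self, kind: str) -> int:
        oid = self.next_id
        self.next_id += 1
        self.otus[oid] = OTU(id=oid, kind=kind, members=[])
        return oid

    def tag_to_otu(self) -> dict[str, int]:
        return {t.seq: o for t, o in zip(self.tags, self.otu_of)}

    def merge_into(self, target: int, sources: Sequence[int]) -> None:
        """Fold source OTUs into target, reassigning their placed tags."""
        srcset = set(sources) - {target}
        if not srcset:
            return
        for idx, oid in enumerate(self.otu_of):
            if oid in srcset:
                self.otu_of[idx] = target
        tgt = self.otus[target]
        for oid in sorted(srcset):
            tgt.members.extend(self.otus[oid].members)
            w, codes, tag = self.reps[oid]
            self._update_rep(target, w, codes, tag)
            del self.otus[oid]
            del self.reps[oid]

    # -- search ---------------------------------------------------------
    def rank_candidates(self, qcodes: np.ndarray, qlen: int) -> tuple[np.ndarray, np.ndarray]:
        """Placed-tag indices admitted by the f_max prescreen, sorted by
        ascending k-word distance (stable, so placement order breaks ties)."""
        data, off, lens = self._kstore.arrays()
        if self.rank_targets == "all":
            idx = np.arange(self._kstore.n, dtype=np.int64)
        else:
            rep_rows = set()
            for oid in self.reps:
                _, rcodes, rtag = self.reps[oid]
                rep_rows.add(self._row_of(rtag))
            idx = np.asarray(sorted(rep_rows), np.int64)
        qk = _kernels.encode_kmers(qcodes, self.kp.k)
        out = np.empty(idx.shape[0], np.float64)
        _kernels.kmer_dist_to_many(qk, qlen, data, off, lens, idx, self.kp.k, out)
        keep = out <= self.kp.f_max
        idx = idx[keep]
        out = out[keep]
        order = np.argsort(out, kind="stable")
        return idx[order], out[order]

    def _row_of(self, tag: Tag) -> int:
        for i, t in enumerate(self.tags):
            if t is tag:
                return i
        raise KeyError(tag.seq)


def build_index(haotus: Sequence[OTU], kp: KmerParams,
                pre: PreclusterResult | None = None,
                rank_targets: str = "all") -> OtuIndex:
    """Index the stage-1 HAOTUs; seed tags carry their post-precluster
    weight so 'most abundant hit tag' reflects the denoised abundances."""
    index = OtuIndex(kp, rank_targets=rank_targets)
    weights = pre.seed_weight if pre is not None else {}
    for otu in haotus:
        oid = index.new_otu("HAOTU")
        assert oid == otu.id, "HAOTUs must be indexed in stage-1 order"
        for tag, via in otu.members:
            index.place(tag, oid, via, weight=weights.get(tag.rank, tag.abundance))
    return index


def precluster2_shortcut(rare_tag: Tag | str, index: OtuIndex, d: float) -> int | None:
    """Alignment-free placement: scan OTU representatives in creation
    order and return the first whose position-wise (gap-free) distance is
    strictly below ``d``; None when no representative qualifies."""
    seq = rare_tag.seq if isinstance(rare_tag, Tag) else rare_tag
    qcodes = encode(seq)
    for oid, (_w, rcodes, _t) in index.reps.items():
        if _kernels.direct_distance(qcodes, rcodes) < d:
            return oid
    return None


def greedy_assign(rare_tag: Tag, index: OtuIndex, sp: SearchParams,
                  ap: AlignmentParams, kp: KmerParams,
                  stats: Stage2Stats | None = None) -> int:
    """Batched k-word-ordered NW search followed by the five-case rule.

    Returns the case number applied (1-5) and mutates the index.
    """
    stats = stats if stats is not None else Stage2Stats()
    qcodes = encode(rare_tag.seq)
    cand, _kd = index.rank_candidates(qcodes, len(rare_tag.seq))
    go, ge, endc = _gap_scores(ap)
    hits: list[int] = []
    pos = 0
    while pos < cand.shape[0]:
        batch = cand[pos:pos + sp.batch]
        batch_hits = 0
        for w in batch:
            stats.nw_alignments += 1
            _, dd = _kernels.pair_nw(qcodes, index.codes[int(w)],
                                     ap.match, ap.mismatch, go, ge, endc,
                                     ap.exclude_end_gaps, ap.count_runs)
            if dd <= sp.d:
                hits.append(int(w))
                batch_hits += 1
        pos += len(batch)
        if batch_hits == 0:
            break

    if not hits:
        oid = index.new_otu("LAOTU")
        index.place(rare_tag, oid, "greedy")
        case = 1
    else:
        hit_otus = sorted({index.otu_of[w] for w in hits})
        ha = [o for o in hit_otus if index.otus[o].kind == "HAOTU"]
        la = [o for o in hit_otus if index.otus[o].kind == "LAOTU"]
        if len(hit_otus) == 1:
            index.place(rare_tag, hit_otus[0], "greedy")
            case = 2
        elif not la:
            # best hit tag among HAOTU hits; ties -> earlier OTU id
            best = max((w for w in hits if index.otu_of[w] in ha),
                       key=lambda w: (index.weights[w], -index.otu_of[w]))
            index.place(rare_tag, index.otu_of[best], "greedy")
            case = 3
        elif not ha:
            target = la[0]
            index.merge_into(target, la[1:])
            index.place(rare_tag, target, "greedy")
            case = 4
        else:
            best = max((w for w in hits if index.otu_of[w] in ha),
                       key=lambda w: (index.weights[w], -index.otu_of[w]))
            target = index.otu_of[best]
            index.merge_into(target, la)
            index.place(rare_tag, target, "greedy")
            case = 5
    stats.case_counts[case] += 1
    return case


def run_stage2(split: TagSplit, haotus: Sequence[OTU], sp: SearchParams,
               ap: AlignmentParams, kp: KmerParams,
               pre: PreclusterResult | None = None,
               rank_targets: str = "all",
               trace: bool = False) -> tuple[list[OTU], Stage2Stats, OtuIndex]:
    """Process rare tags in abundance order through the shortcut and the
    greedy search; returns the final OTU list (a partition of all tags)."""
    index = build_index(haotus, kp, pre=pre, rank_targets=rank_targets)
    stats = Stage2Stats()
    for tag in split.rare:
        if sp.shortcut:
            oid = precluster2_shortcut(tag, index, sp.d)
            if oid is not None:
                index.place(tag, oid, "precluster2")
                stats.shortcut_placements += 1
                if trace:
                    stats.trace.append((tag.seq, 0, oid))
                continue
        case = greedy_assign(tag, index, sp, ap, kp, stats)
        if trace:
            stats.trace.append((tag.seq, case, index.otu_of[-1]))
    final = [index.otus[oid] for oid in sorted(index.otus)]
    return final, stats, index
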