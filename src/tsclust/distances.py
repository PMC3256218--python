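"""Pairwise distances: k-word prescreen, affine-gap NW alignment, and the
sparse all-vs-all distance set used by stage-1 clustering.

The NW distance is the fraction of differing columns in a score-optimal
global alignment.  With end-gap exclusion (-x) terminal gap columns are
free in scoring and trimmed before counting.  Platform "illumina" counts
every gap column as a difference; platform "454" scores gap extensions
and end gaps 0 and counts each maximal gap run as a single indel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import _kernels
from .params import AlignmentParams, KmerParams, ParameterError

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
# IUPAC ambiguity codes: encoded >= 4, never match any base (incl. themselves)
for _i, _c in enumerate("RYSWKMBDHVN"):
    _CODE[ord(_c)] = 4 + _i
    _CODE[ord(_c.lower())] = 4 + _i


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (A,C,G,T -> 0..3, IUPAC -> >= 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ParameterError(f"invalid sequence character {bad!r}")
    return codes


def _gap_scores(p: AlignmentParams) -> tuple[float, float, float]:
    """(gap_open, effective gap_extend, end-gap per-column cost).

    End-gap columns are charged like extensions (no open): e per column
    on Illumina, 0 on 454.  The -x flag does not change scoring; it trims
    terminal gap columns from the distance.
    """
    ge = 0.0 if p.platform == "454" else p.gap_extend
    endc = 0.0 if p.platform == "454" else p.gap_extend
    return p.gap_open, ge, endc


def kmer_distance(s1: str, s2: str, k: int = 6) -> float:
    """1 - (shared k-words) / (min(len) - k + 1); 0 for identical inputs."""
    if min(len(s1), len(s2)) < k:
        raise ParameterError(f"sequences must be at least k={k} long")
    a = _kernels.encode_kmers(encode(s1), k)
    b = _kernels.encode_kmers(encode(s2), k)
    denom = min(len(s1), len(s2)) - k + 1
    return 1.0 - _kernels.kmer_shared(a, b) / denom


def nw_align(s1: str, s2: str, p: AlignmentParams | None = None) -> tuple[str, str, float]:
    """Optimal global alignment; returns the two gapped strings and the score."""
    p = p or AlignmentParams()
    if not s1 or not s2:
        raise ParameterError("cannot align an empty sequence")
    go, ge, endc = _gap_scores(p)
    score, path, plen = _kernels.align_core(
        encode(s1), encode(s2), p.match, p.mismatch, go, ge, endc)
    a1 = []
    a2 = []
    i = j = 0
    for t in range(plen):
        c = path[t]
        if c == _kernels.DIAG:
            a1.append(s1[i]); a2.append(s2[j]); i += 1; j += 1
        elif c == _kernels.UP:
            a1.append(s1[i]); a2.append("-"); i += 1
        else:
            a1.append("-"); a2.append(s2[j]); j += 1
    return "".join(a1), "".join(a2), float(score)


def nw_distance(a1: str, a2: str, p: AlignmentParams | None = None) -> float:
    """Fractional difference of an explicit (gapped) alignment.

    Counts substitutions plus gap columns (or gap runs in 454 mode) over
    the alignment length after trimming terminal gap columns when -x is
    set.  A trimmed span of zero columns scores 1.0.
    """
    p = p or AlignmentParams()
    if len(a1) != len(a2):
        raise ParameterError("aligned strings must have equal length")
    cols = list(zip(a1, a2))
    if any(c1 == "-" and c2 == "-" for c1, c2 in cols):
        raise AssertionError("alignment contains an all-gap column")
    lo, hi = 0, len(cols)
    if p.exclude_end_gaps:
        while lo < hi and "-" in cols[lo]:
            lo += 1
        while hi > lo and "-" in cols[hi - 1]:
            hi -= 1
    if hi == lo:
        return 1.0
    mism = gapcols = gapruns = 0
    prev_gap = None  # 1: gap in a1, 2: gap in a2
    for c1, c2 in cols[lo:hi]:
        if c1 == "-" or c2 == "-":
            which = 1 if c1 == "-" else 2
            gapcols += 1
            if which != prev_gap:
                gapruns += 1
            prev_gap = which
        else:
            if c1.upper() != c2.upper() or c1.upper() not in "ACGT":
                mism += 1
            prev_gap = None
    gaps = gapruns if p.count_runs else gapcols
    return (mism + gaps) / (hi - lo)


def nw_pair_distance(s1: str, s2: str, p: AlignmentParams | None = None) -> float:
    """Align two sequences and return the NW distance in one step."""
    p = p or AlignmentParams()
    go, ge, endc = _gap_scores(p)
    _, d = _kernels.pair_nw(encode(s1), encode(s2), p.match, p.mismatch,
                            go, ge, endc, p.exclude_end_gaps, p.count_runs)
    return float(d)


@dataclass(frozen=True)
class PairDistance:
    i: int
    j: int
    d: float


@dataclass
class SparseDistanceSet:
    """Pairwise NW distances retained after prescreening and a storage cap.

    Pairs absent from the set are interpreted as d > cap (either the
    k-word prescreen rejected them or the computed distance exceeded the
    cap).  ``n_alignments`` counts NW alignments actually performed.
    """

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    cap: float
    n_tags: int
    n_alignments: int = 0

    def __len__(self) -> int:
        return int(self.i.shape[0])

    def __iter__(self) -> Iterator[PairDistance]:
        for a, b, dd in zip(self.i, self.j, self.d):
            yield PairDistance(int(a), int(b), float(dd))

    def adjacency(self, max_d: float | None = None) -> list[list[tuple[int, float]]]:
        """Per-tag neighbour lists (both directions), optionally thresholded."""
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n_tags)]
        for a, b, dd in zip(self.i, self.j, self.d):
            if max_d is None or dd <= max_d:
                adj[int(a)].append((int(b), float(dd)))
                adj[int(b)].append((int(a), float(dd)))
        return adj

    def to_text(self, path: str | Path) -> None:
        """Write 3-column `i j d` text (ESPRIT/mothur column dialect)."""
        with open(path, "w") as fh:
            for a, b, dd in zip(self.i, self.j, self.d):
                fh.write(f"{int(a)} {int(b)} {dd:.6f}\n")

    @classmethod
    def from_text(cls, path: str | Path, cap: float, n_tags: int) -> "SparseDistanceSet":
        ii: list[int] = []
        jj: list[int] = []
        dd: list[float] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                a, b, x = int(parts[0]), int(parts[1]), float(parts[2])
                ii.append(min(a, b))
                jj.append(max(a, b))
                dd.append(x)
        return cls(np.asarray(ii, np.int64), np.asarray(jj, np.int64),
                   np.asarray(dd, np.float64), cap=cap, n_tags=n_tags)


def _seqs_of(tags: Sequence) -> list[str]:
    return [t.seq if hasattr(t, "seq") else str(t) for t in tags]


def sparse_all_pairs(tags: Sequence, kp: KmerParams | None = None,
                     ap: AlignmentParams | None = None,
                     cap: float = 0.10) -> SparseDistanceSet:
    """All-vs-all NW distances for the abundant group, k-word prescreened.

    Only pairs whose k-word distance is <= f_max are aligned, and only
    distances <= cap are stored.
    """
    kp = kp or KmerParams()
    ap = ap or AlignmentParams()
    seqs = _seqs_of(tags)
    n = len(seqs)
    if n == 0:
        return SparseDistanceSet(np.empty(0, np.int64), np.empty(0, np.int64),
                                 np.empty(0, np.float64), cap, 0, 0)
    codes = [encode(s) for s in seqs]
    seqcat = np.concatenate(codes) if codes else np.empty(0, np.uint8)
    soff = np.zeros(n + 1, np.int64)
    np.cumsum([len(c) for c in codes], out=soff[1:])
    kms = [_kernels.encode_kmers(c, kp.k) for c in codes]
    kmercat = np.concatenate(kms) if kms else np.empty(0, np.int64)
    koff = np.zeros(n + 1, np.int64)
    np.cumsum([len(a) for a in kms], out=koff[1:])
    go, ge, endc = _gap_scores(ap)

    capacity = max(1024, 8 * n)
    while True:
        out_i = np.empty(capacity, np.int64)
        out_j = np.empty(capacity, np.int64)
        out_d = np.empty(capacity, np.float64)
        stored, aligned, needed = _kernels.sparse_pairs(
            seqcat, soff, kmercat, koff, kp.k, kp.f_max,
            ap.match, ap.mismatch, go, ge, endc,
            ap.exclude_end_gaps, ap.count_runs, cap,
            out_i, out_j, out_d)
        if needed <= capacity:
            return SparseDistanceSet(out_i[:stored].copy(), out_j[:stored].copy(),
                                     out_d[:stored].copy(), cap, n, aligned)
        capacity = needed
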