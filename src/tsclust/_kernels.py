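"""Numba kernels: affine-gap global alignment, k-word counting, pair sweeps.

Sequences are handled as uint8 code arrays (A,C,G,T -> 0..3; ambiguity
codes >= 4 never match anything, including themselves).  All kernels are
serial and deterministic; tie-breaks are fixed (diagonal, then gap in the
second sequence, then gap in the first).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# path codes emitted by the traceback
DIAG = 0  # consume one base of each sequence
UP = 1    # consume s1, gap column in s2
LEFT = 2  # consume s2, gap column in s1


@njit(cache=True)
def align_core(x, y, a, b, go, ge, endc):
    """Gotoh DP with boundary (end-gap) columns charged ``endc`` each.

    Returns (score, path, path_len); ``path`` holds DIAG/UP/LEFT codes in
    alignment order.  Internal gap runs cost go + ge*(L-1); terminal runs
    cost endc per column (endc >= ge >= go, so the boundary convention is
    an upper envelope and the maximum is exact).
    """
    m = x.shape[0]
    n = y.shape[0]
    M = np.full((m + 1, n + 1), NEG)
    D = np.full((m + 1, n + 1), NEG)  # ends with UP (gap in s2)
    I = np.full((m + 1, n + 1), NEG)  # ends with LEFT (gap in s1)
    pM = np.zeros((m + 1, n + 1), np.int8)
    pD = np.zeros((m + 1, n + 1), np.int8)
    pI = np.zeros((m + 1, n + 1), np.int8)

    M[0, 0] = 0.0
    for j in range(1, n + 1):
        I[0, j] = endc * j
    for i in range(1, m + 1):
        D[i, 0] = endc * i

    for i in range(1, m + 1):
        xi = x[i - 1]
        for j in range(1, n + 1):
            sub = a if (xi == y[j - 1] and xi < 4) else b
            # diagonal: predecessor preference M > D > I on ties
            best = M[i - 1, j - 1]
            p = 0
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                p = 1
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
                p = 2
            M[i, j] = sub + best
            pM[i, j] = p
            # gap in s2 (UP)
            best = M[i - 1, j] + go
            p = 0
            if D[i - 1, j] + ge > best:
                best = D[i - 1, j] + ge
                p = 1
            if I[i - 1, j] + go > best:
                best = I[i - 1, j] + go
                p = 2
            D[i, j] = best
            pD[i, j] = p
            # gap in s1 (LEFT)
            best = M[i, j - 1] + go
            p = 0
            if D[i, j - 1] + go > best:
                best = D[i, j - 1] + go
                p = 1
            if I[i, j - 1] + ge > best:
                best = I[i, j - 1] + ge
                p = 2
            I[i, j] = best
            pI[i, j] = p

    # termination: allow trailing gap runs at endc per column; prefer the
    # corner, then the shortest trailing run in s2, then in s1
    bi = m
    bj = n
    bs = 0
    score = M[m, n]
    if D[m, n] > score:
        score = D[m, n]
        bs = 1
    if I[m, n] > score:
        score = I[m, n]
        bs = 2
    for i in range(m - 1, -1, -1):
        cell = M[i, n]
        s = 0
        if D[i, n] > cell:
            cell = D[i, n]
            s = 1
        if I[i, n] > cell:
            cell = I[i, n]
            s = 2
        cand = cell + endc * (m - i)
        if cand > score:
            score = cand
            bi = i
            bj = n
            bs = s
    for j in range(n - 1, -1, -1):
        cell = M[m, j]
        s = 0
        if D[m, j] > cell:
            cell = D[m, j]
            s = 1
        if I[m, j] > cell:
            cell = I[m, j]
            s = 2
        cand = cell + endc * (n - j)
        if cand > score:
            score = cand
            bi = m
            bj = j
            bs = s
    if m == 0 or n == 0:
        # degenerate: one sequence empty; pure gap alignment
        score = endc * (m + n)

    path = np.empty(m + n, np.int8)
    pos = 0
    # trailing gaps first (built in reverse)
    if bi < m:
        for _ in range(m - bi):
            path[pos] = UP
            pos += 1
    elif bj < n:
        for _ in range(n - bj):
            path[pos] = LEFT
            pos += 1
    i = bi
    j = bj
    s = bs
    while i > 0 or j > 0:
        if i == 0:
            path[pos] = LEFT
            pos += 1
            j -= 1
        elif j == 0:
            path[pos] = UP
            pos += 1
            i -= 1
        elif s == 0:
            path[pos] = DIAG
            pos += 1
            s = pM[i, j]
            i -= 1
            j -= 1
        elif s == 1:
            path[pos] = UP
            pos += 1
            s = pD[i, j]
            i -= 1
        else:
            path[pos] = LEFT
            pos += 1
            s = pI[i, j]
            j -= 1
    # reverse into alignment order
    out = np.empty(pos, np.int8)
    for t in range(pos):
        out[t] = path[pos - 1 - t]
    return score, out, pos


@njit(cache=True)
def dist_from_path(x, y, path, trim_ends, count_runs):
    """Fractional difference of an alignment given as a path-code array.

    trim_ends drops terminal gap columns before counting; count_runs
    counts each maximal gap run once (454 convention) instead of each
    gap column.  An alignment whose trimmed span is empty scores 1.0.
    """
    plen = path.shape[0]
    lo = 0
    while lo < plen and path[lo] != DIAG:
        lo += 1
    hi = plen
    while hi > lo and path[hi - 1] != DIAG:
        hi -= 1
    if not trim_ends:
        lo = 0
        hi = plen
    if hi == lo:
        return 1.0
    # advance i/j over the skipped leading columns
    i = 0
    j = 0
    for t in range(lo):
        c = path[t]
        if c == DIAG:
            i += 1
            j += 1
        elif c == UP:
            i += 1
        else:
            j += 1
    mism = 0
    gapcols = 0
    gapruns = 0
    prev = np.int8(-1)
    for t in range(lo, hi):
        c = path[t]
        if c == DIAG:
            xi = x[i]
            if xi != y[j] or xi >= 4:
                mism += 1
            i += 1
            j += 1
        else:
            gapcols += 1
            if c != prev:
                gapruns += 1
            if c == UP:
                i += 1
            else:
                j += 1
        prev = c
    gaps = gapruns if count_runs else gapcols
    return (mism + gaps) / (hi - lo)


@njit(cache=True)
def pair_nw(x, y, a, b, go, ge, endc, trim_ends, count_runs):
    """Score-optimal alignment plus its fractional distance."""
    score, path, _ = align_core(x, y, a, b, go, ge, endc)
    return score, dist_from_path(x, y, path, trim_ends, count_runs)


@njit(cache=True)
def direct_distance(x, y):
    """Gap-free 5'->3' comparison: mismatches over the shorter length plus
    the length difference, divided by the longer length."""
    la = x.shape[0]
    lb = y.shape[0]
    s = min(la, lb)
    l = max(la, lb)
    mism = 0
    for i in range(s):
        if x[i] != y[i] or x[i] >= 4:
            mism += 1
    return (mism + (l - s)) / l


@njit(cache=True)
def encode_kmers(codes, k):
    """Sorted multiset of k-words as base-4 integers; windows containing
    an ambiguity code are dropped."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, np.int64)
    out = np.empty(n, np.int64)
    cnt = 0
    for i in range(n):
        v = 0
        ok = True
        for t in range(k):
            c = codes[i + t]
            if c >= 4:
                ok = False
                break
            v = v * 4 + c
        if ok:
            out[cnt] = v
            cnt += 1
    res = np.sort(out[:cnt])
    return res


@njit(cache=True)
def kmer_shared(a, b):
    """Sum over words of min(count_a, count_b), via sorted-multiset merge."""
    i = 0
    j = 0
    c = 0
    while i < a.shape[0] and j < b.shape[0]:
        if a[i] == b[j]:
            c += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return c


@njit(cache=True)
def sparse_pairs(seqcat, soff, kmercat, koff, k, f_max,
                 a, b, go, ge, endc, trim_ends, count_runs, cap,
                 out_i, out_j, out_d):
    """All-vs-all sweep: k-word prescreen, NW on survivors, store d <= cap.

    Returns (stored, aligned, needed); ``needed`` > len(out_i) signals the
    caller to retry with larger output buffers (entries beyond capacity
    are counted but not written).
    """
    n = soff.shape[0] - 1
    stored = 0
    aligned = 0
    needed = 0
    capacity = out_i.shape[0]
    for i in range(n):
        xi = seqcat[soff[i]:soff[i + 1]]
        ki = kmercat[koff[i]:koff[i + 1]]
        li = xi.shape[0]
        for j in range(i + 1, n):
            xj = seqcat[soff[j]:soff[j + 1]]
            lj = xj.shape[0]
            denom = min(li, lj) - k + 1
            if denom <= 0:
                continue
            shared = kmer_shared(ki, kmercat[koff[j]:koff[j + 1]])
            kd = 1.0 - shared / denom
            if kd > f_max:
                continue
            aligned += 1
            _, d = pair_nw(xi, xj, a, b, go, ge, endc, trim_ends, count_runs)
            if d <= cap:
                needed += 1
                if stored < capacity:
                    out_i[stored] = i
                    out_j[stored] = j
                    out_d[stored] = d
                    stored += 1
    return stored, aligned, needed


@njit(cache=True)
def kmer_dist_to_many(qk, qlen, kmercat, koff, lens, idx, k, out):
    """k-word distance from one query to the targets listed in ``idx``."""
    for t in range(idx.shape[0]):
        w = idx[t]
        denom = min(qlen, lens[w]) - k + 1
        if denom <= 0:
            out[t] = 1.0
            continue
        shared = kmer_shared(qk, kmercat[koff[w]:koff[w + 1]])
        out[t] = 1.0 - shared / denom
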