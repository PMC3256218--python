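"""Independent oracles used by the test suite.

These deliberately avoid the package's DP/agglomeration code paths:
alignment scores come from a memoized recursion over alignment moves
(cross-checked against pure path enumeration), clustering from
scipy.cluster.hierarchy on a dense matrix, single linkage additionally
from plain union-find over thresholded edges.
"""

from __future__ import annotations

import functools
import sys

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def oracle_align_score(x: str, y: str, match=1.0, mismatch=-1.0,
                       gap_open=-10.0, gap_extend=-1.0,
                       platform="illumina") -> float:
    """Optimal global alignment score by memoized recursion over moves.

    Internal gap runs cost gap_open + gap_extend*(L-1); end-gap columns
    (before the gapped sequence starts or after it ends) cost gap_extend
    per column on illumina and 0 on 454, which also zeroes extensions.
    """
    ge = 0.0 if platform == "454" else gap_extend
    endc = 0.0 if platform == "454" else gap_extend
    m, n = len(x), len(y)
    sys.setrecursionlimit(10000)

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == m and j == n:
            return 0.0
        cands = []
        if i < m and j < n:
            s = match if x[i] == y[j] else mismatch
            cands.append(s + rec(i + 1, j + 1, "M"))
        if i < m:  # gap column in y
            c = endc if (j == 0 or j == n) else (ge if prev == "D" else gap_open)
            cands.append(c + rec(i + 1, j, "D"))
        if j < n:  # gap column in x
            c = endc if (i == 0 or i == m) else (ge if prev == "I" else gap_open)
            cands.append(c + rec(i, j + 1, "I"))
        return max(cands)

    return rec(0, 0, "")


def enumerate_align_score(x: str, y: str, **kw) -> float:
    """Pure exhaustive enumeration of every alignment path (tiny inputs)."""
    match = kw.get("match", 1.0)
    mismatch = kw.get("mismatch", -1.0)
    gap_open = kw.get("gap_open", -10.0)
    gap_extend = kw.get("gap_extend", -1.0)
    platform = kw.get("platform", "illumina")
    ge = 0.0 if platform == "454" else gap_extend
    endc = 0.0 if platform == "454" else gap_extend

    def paths(i, j):
        if i == len(x) and j == len(y):
            yield []
            return
        if i < len(x) and j < len(y):
            for p in paths(i + 1, j + 1):
                yield [("M", x[i], y[j])] + p
        if i < len(x):
            for p in paths(i + 1, j):
                yield [("D", x[i], "-")] + p
        if j < len(y):
            for p in paths(i, j + 1):
                yield [("I", "-", y[j])] + p

    def score(cols):
        n = len(cols)
        lo = 0
        while lo < n and cols[lo][0] != "M":
            lo += 1
        hi = n
        while hi > lo and cols[hi - 1][0] != "M":
            hi -= 1
        s = 0.0
        prev = None
        for t, (kind, cx, cy) in enumerate(cols):
            if kind == "M":
                s += match if cx == cy else mismatch
                prev = None
            else:
                if t < lo or t >= hi:
                    s += endc
                else:
                    s += ge if prev == kind else gap_open
                prev = kind
        return s

    return max(score(p) for p in paths(0, 0))


def scipy_clusters(D: np.ndarray, d: float, linkage_mode: str) -> set[frozenset[int]]:
    """Agglomerative clusters of a dense square distance matrix cut at d."""
    method = {"cl": "complete", "al": "average", "sl": "single"}[linkage_mode]
    n = D.shape[0]
    if n == 1:
        return {frozenset([0])}
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=d, criterion="distance")
    out: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in out.values()}


def unionfind_components(n: int, edges: list[tuple[int, int, float]],
                         d: float) -> set[frozenset[int]]:
    """Connected components of the graph with edge weights <= d."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, w in edges:
        if w <= d:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in comps.values()}


def random_sparse_instance(rng: np.random.Generator, n_max: int = 50,
                           cap: float = 0.10):
    """A random clustering instance: dense matrix with some pairs beyond
    the cap (missing), plus the equivalent sparse entry list."""
    n = int(rng.integers(2, n_max + 1))
    D = np.zeros((n, n))
    entries = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                val = float(rng.uniform(0.0, cap))
                entries.append((i, j, val))
            else:
                val = cap + 1e-6  # missing-pair constant
            D[i, j] = D[j, i] = val
    return n, D, entries
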