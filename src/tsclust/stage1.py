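"""Stage 1: denoise the abundant group by one sequential single-linkage
precluster pass at 0.02, then agglomerate the surviving seeds at the
target distance with complete, average, or single linkage (HAOTUs).

The sparse distance set drives both steps; a pair absent from it (k-word
prescreen rejection or distance above the storage cap) is treated as
definitely above any usable threshold (cap + eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .derep import Tag
from .distances import SparseDistanceSet
from .params import ParameterError

MISSING_EPS = 1e-6

Via = Literal["direct", "precluster1", "precluster2", "greedy"]


@dataclass
class OTU:
    """A cluster of tags; HAOTU if created in stage 1, LAOTU in stage 2."""

    id: int
    kind: Literal["HAOTU", "LAOTU"]
    members: list[tuple[Tag, str]] = field(default_factory=list)

    @property
    def tags(self) -> list[Tag]:
        return [t for t, _ in self.members]

    @property
    def representative(self) -> Tag:
        """Most abundant member; ties go to the lexicographically smaller
        sequence (deterministic across runs)."""
        return min(self.tags, key=lambda t: (-t.abundance, t.seq))

    @property
    def total_abundance(self) -> int:
        return sum(t.abundance for t in self.tags)

    @property
    def read_ids(self) -> list[str]:
        out: list[str] = []
        for t in self.tags:
            out.extend(t.read_ids if t.read_ids else [t.exemplar_id])
        return out


@dataclass
class PreclusterResult:
    seeds: list[Tag]
    merged_into: dict[int, int]           # absorbed tag rank -> seed tag rank
    mode: Literal["add-abundance", "literal-plus-one"]
    seed_weight: dict[int, int]           # seed rank -> post-merge abundance


def precluster_denoise(abundant: Sequence[Tag], dset: SparseDistanceSet,
                       threshold: float = 0.02,
                       literal: bool = False) -> PreclusterResult:
    """One sequential single-linkage denoising pass over the abundant group.

    Tags are visited in abundance order; each seed absorbs every still
    unabsorbed lower-ranked tag within ``threshold`` NW distance, and
    absorbed tags are never re-examined.  The seed's weight grows by the
    absorbed tag's abundance (default) or by 1 (``literal``, the printed
    convention); memberships are identical either way.

    ``dset`` indices must correspond to positions in ``abundant``.
    """
    n = len(abundant)
    if dset.n_tags != n:
        raise ParameterError("distance set does not match the abundant group")
    adj = dset.adjacency(max_d=threshold)
    absorbed = np.zeros(n, dtype=bool)
    merged_into: dict[int, int] = {}
    seed_weight: dict[int, int] = {}
    seeds: list[Tag] = []
    for p in range(n):
        if absorbed[p]:
            continue
        seed = abundant[p]
        seeds.append(seed)
        weight = seed.abundance
        for q, _d in adj[p]:
            if q > p and not absorbed[q]:
                absorbed[q] = True
                merged_into[abundant[q].rank] = seed.rank
                weight += 1 if literal else abundant[q].abundance
        seed_weight[seed.rank] = weight
    return PreclusterResult(seeds=seeds, merged_into=merged_into,
                            mode="literal-plus-one" if literal else "add-abundance",
                            seed_weight=seed_weight)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _agglomerate_dense(D: np.ndarray, d: float, linkage: str) -> list[list[int]]:
    """Greedy agglomeration on a dense matrix; merges while the closest
    cluster pair is within ``d``.  Equal-distance ties merge the pair with
    the smallest (row-major) indices."""
    n = D.shape[0]
    W = D.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    while True:
        flat = np.argmin(W)
        i, j = divmod(int(flat), n)
        if W[i, j] > d:
            break
        if j < i:
            i, j = j, i
        if linkage == "cl":
            row = np.maximum(W[i], W[j])
        elif linkage == "al":
            row = (sizes[i] * W[i] + sizes[j] * W[j]) / (sizes[i] + sizes[j])
        else:
            row = np.minimum(W[i], W[j])
        W[i] = row
        W[:, i] = row
        W[i, i] = np.inf
        W[j, :] = np.inf
        W[:, j] = np.inf
        sizes[i] += sizes[j]
        active[j] = False
        members[i].extend(members[j])
        members[j] = []
    return [sorted(members[i]) for i in range(n) if active[i]]


def hierarchical_cluster(seeds: Sequence[Tag], dset: SparseDistanceSet,
                         d: float, linkage: str,
                         indices: Sequence[int] | None = None) -> list[OTU]:
    """Agglomerative clustering of precluster seeds cut at distance ``d``.

    SL yields the connected components of the graph of stored distances
    <= d.  CL and AL agglomerate greedily with missing pairs valued at
    cap + eps; since no merge can cross a single-linkage component at the
    same threshold, the dense agglomeration runs per component.

    ``indices`` maps each seed to its row in ``dset`` (defaults to 0..n-1).
    """
    if linkage not in ("cl", "al", "sl"):
        raise ParameterError(f"unknown linkage {linkage!r}")
    if d > dset.cap:
        raise ParameterError(
            f"threshold {d} exceeds the sparse-matrix cap {dset.cap}; "
            "recompute distances with a larger --cap")
    n = len(seeds)
    if indices is None:
        indices = list(range(n))
        if dset.n_tags < n:
            raise ParameterError("distance set smaller than the seed list")
    pos = {int(g): t for t, g in enumerate(indices)}

    edges: list[tuple[int, int, float]] = []
    for a, b, dd in zip(dset.i, dset.j, dset.d):
        pa = pos.get(int(a))
        pb = pos.get(int(b))
        if pa is not None and pb is not None:
            edges.append((pa, pb, float(dd)))

    uf = _UnionFind(n)
    for pa, pb, dd in edges:
        if dd <= d:
            uf.union(pa, pb)
    comps: dict[int, list[int]] = {}
    for t in range(n):
        comps.setdefault(uf.find(t), []).append(t)
    comp_list = [sorted(v) for _, v in sorted(comps.items())]

    if linkage == "sl":
        clusters = comp_list
    else:
        miss = dset.cap + MISSING_EPS
        by_comp: dict[int, int] = {}
        for ci, comp in enumerate(comp_list):
            for t in comp:
                by_comp[t] = ci
        comp_edges: list[list[tuple[int, int, float]]] = [[] for _ in comp_list]
        for pa, pb, dd in edges:
            if by_comp[pa] == by_comp[pb]:
                comp_edges[by_comp[pa]].append((pa, pb, dd))
        clusters = []
        for ci, comp in enumerate(comp_list):
            if len(comp) == 1:
                clusters.append(comp)
                continue
            local = {t: k for k, t in enumerate(comp)}
            D = np.full((len(comp), len(comp)), miss)
            np.fill_diagonal(D, 0.0)
            for pa, pb, dd in comp_edges[ci]:
                la, lb = local[pa], local[pb]
                # keep the smaller value if duplicated
                if dd < D[la, lb]:
                    D[la, lb] = D[lb, la] = dd
            for sub in _agglomerate_dense(D, d, linkage):
                clusters.append(sorted(comp[k] for k in sub))
        clusters.sort(key=lambda c: c[0])

    otus = []
    for oid, cluster in enumerate(clusters):
        otus.append(OTU(id=oid, kind="HAOTU",
                        members=[(seeds[t], "direct") for t in cluster]))
    return otus


def attach_precluster_members(otus: Sequence[OTU], pre: PreclusterResult,
                              abundant: Sequence[Tag]) -> None:
    """Add precluster-absorbed tags to the OTU holding their seed."""
    seed_otu: dict[int, OTU] = {}
    for otu in otus:
        for tag, _via in otu.members:
            seed_otu[tag.rank] = otu
    by_rank = {t.rank: t for t in abundant}
    for absorbed_rank, seed_rank in pre.merged_into.items():
        seed_otu[seed_rank].members.append((by_rank[absorbed_rank], "precluster1"))
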