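"""Parameter containers for alignment, k-mer screening, and clustering.

Defaults mirror the pipeline's shipped flag set:
``-g -10 -e -1 -a 1 -b -1 -k 6 -f 0.5 -d 0.03 -n 10 -x 1 -s 10 -m al``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

Platform = Literal["illumina", "454"]
Linkage = Literal["cl", "al", "sl"]
GapCountMode = Literal["column", "run"]


class ParameterError(ValueError):
    """A parameter violates its documented range or consistency rule."""


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment scoring and distance conventions.

    match/mismatch/gap_open/gap_extend are the NW scores (a, b, g, e).
    A gap run of length L costs ``gap_open + gap_extend * (L - 1)``.

    ``exclude_end_gaps`` (the -x flag) trims terminal gap columns before
    the distance is counted.  Scoring charges end-gap columns like
    extensions: e per column on "illumina" (whose errors are mismatches,
    so every gap column also counts one difference), 0 on "454", which
    additionally scores continuous extension gaps 0 and counts each gap
    run as a single indel, matching homopolymer error structure.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    exclude_end_gaps: bool = True
    platform: Platform = "illumina"
    # Override the per-column vs per-run gap counting implied by platform.
    gap_count_mode: GapCountMode | None = None

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ParameterError("gap penalties must be <= 0")
        if self.match <= self.mismatch:
            raise ParameterError("match score must exceed mismatch score")
        if self.platform not in ("illumina", "454"):
            raise ParameterError(f"unknown platform {self.platform!r}")

    @property
    def count_runs(self) -> bool:
        """True when a gap run counts as one difference (454 convention)."""
        if self.gap_count_mode is not None:
            return self.gap_count_mode == "run"
        return self.platform == "454"


@dataclass(frozen=True)
class KmerParams:
    """k-word prescreen: word length k and admission ceiling f_max."""

    k: int = 6
    f_max: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if not 0.0 <= self.f_max <= 1.0:
            raise ParameterError("f_max must lie in [0, 1]")


@dataclass(frozen=True)
class SearchParams:
    """Second-stage greedy search: threshold d, NW batch size, shortcut toggle."""

    d: float = 0.03
    batch: int = 10
    shortcut: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ParameterError("assignment threshold d must lie in (0, 1)")
        if self.batch < 1:
            raise ParameterError("batch size must be >= 1")


@dataclass(frozen=True)
class ClusterParams:
    """Stage-1 clustering: linkage mode, threshold, precluster settings."""

    d: float = 0.03
    linkage: Linkage = "al"
    precluster_threshold: float = 0.02
    precluster_literal: bool = False  # seed gains +1 instead of absorbed abundance
    cap: float = 0.10  # sparse-matrix storage ceiling

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ParameterError("clustering threshold d must lie in (0, 1)")
        if self.linkage not in ("cl", "al", "sl"):
            raise ParameterError(f"unknown linkage {self.linkage!r}")
        if self.cap < self.d:
            raise ParameterError("storage cap must be >= clustering threshold")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (derep cutoff + all component params)."""

    cutoff: int = 3
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    kmer: KmerParams = field(default_factory=KmerParams)
    search: SearchParams = field(default_factory=SearchParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    threads: int = 10
    allow_ambiguous: bool = False
    trace: bool = False

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ParameterError("abundance cutoff must be >= 1")
        if self.threads < 1:
            raise ParameterError("thread count must be >= 1")
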