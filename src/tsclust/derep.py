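"""Dereplication: FASTA reading, collapsing reads into unique tags, and
splitting tags into abundant/rare groups at an abundance cutoff.

Tags are sorted by abundance descending; ties break by lexicographically
smaller sequence so the output is independent of input read order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .params import ParameterError

_VALID = set("ACGT")
_AMBIG = set("RYSWKMBDHVN")


class InputFormatError(ValueError):
    """Malformed or unusable input record."""


@dataclass(frozen=True)
class Read:
    id: str
    seq: str


@dataclass(frozen=True)
class Tag:
    """A unique sequence with its read multiplicity."""

    seq: str
    abundance: int
    rank: int
    exemplar_id: str
    read_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class TagSplit:
    abundant: tuple[Tag, ...]
    rare: tuple[Tag, ...]
    cutoff: int

    @property
    def all_tags(self) -> tuple[Tag, ...]:
        return tuple(sorted(self.abundant + self.rare, key=lambda t: t.rank))


def read_fasta(path: str | Path, allow_ambiguous: bool = False) -> list[Read]:
    """Read a FASTA file into upper-cased Reads, preserving record order.

    Sequences must be over A/C/G/T; with ``allow_ambiguous`` IUPAC codes
    are kept (they mismatch every base during alignment).  Empty records
    raise InputFormatError naming the offender.
    """
    reads: list[Read] = []
    ok = _VALID | _AMBIG if allow_ambiguous else _VALID
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise InputFormatError(f"record {rec.id!r} has an empty sequence")
        bad = set(seq) - ok
        if bad:
            raise InputFormatError(
                f"record {rec.id!r} contains non-ACGT characters {sorted(bad)!r}"
                + ("" if allow_ambiguous else " (use --allow-ambiguous to keep IUPAC codes)"))
        reads.append(Read(id=rec.id, seq=seq))
    return reads


def dereplicate(reads: Iterable[Read]) -> list[Tag]:
    """Collapse identical sequences into Tags sorted by abundance descending.

    Ties break by lexicographically smaller sequence first, making the
    result invariant to input read order; the exemplar id is the first
    read observed with that sequence.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    n_reads = 0
    for r in reads:
        groups[r.seq].append(r.id)
        n_reads += 1
    order = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    tags = [Tag(seq=seq, abundance=len(ids), rank=rank,
                exemplar_id=ids[0], read_ids=tuple(ids))
            for rank, (seq, ids) in enumerate(order)]
    assert sum(t.abundance for t in tags) == n_reads
    return tags


def split_by_cutoff(tags: Sequence[Tag], cutoff: int) -> TagSplit:
    """Partition tags into abundant (>= cutoff) and rare (< cutoff) groups,
    both preserving the global abundance order."""
    if cutoff < 1:
        raise ParameterError("cutoff must be >= 1")
    abundant = tuple(t for t in tags if t.abundance >= cutoff)
    rare = tuple(t for t in tags if t.abundance < cutoff)
    return TagSplit(abundant=abundant, rare=rare, cutoff=cutoff)


def write_derep_fasta(tags: Sequence[Tag], path: str | Path) -> None:
    """Write tags as FASTA with usearch-style `>{exemplar};size=N` headers."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.exemplar_id};size={t.abundance}\n{t.seq}\n")
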