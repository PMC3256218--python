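"""End-to-end pipeline: dereplicate -> split -> stage 1 -> stage 2 ->
writers, plus the output partition validator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .derep import Read, Tag, TagSplit, dereplicate, read_fasta, split_by_cutoff
from .distances import SparseDistanceSet, sparse_all_pairs
from .params import RunConfig
from .stage1 import (OTU, PreclusterResult, attach_precluster_members,
                     hierarchical_cluster, precluster_denoise)
from .stage2 import Stage2Stats, run_stage2


@dataclass
class TscResult:
    otus: list[OTU]
    split: TagSplit
    precluster: PreclusterResult
    dset: SparseDistanceSet
    stage2: Stage2Stats
    config: RunConfig
    n_reads: int

    @property
    def n_haotus(self) -> int:
        return sum(1 for o in self.otus if o.kind == "HAOTU")

    @property
    def n_laotus(self) -> int:
        return sum(1 for o in self.otus if o.kind == "LAOTU")

    def summary(self) -> str:
        c = self.config
        lines = [
            f"reads                 {self.n_reads}",
            f"unique tags           {len(self.split.abundant) + len(self.split.rare)}",
            f"abundant tags (>= {c.cutoff}) {len(self.split.abundant)}",
            f"rare tags             {len(self.split.rare)}",
            f"stage-1 NW alignments {self.dset.n_alignments}",
            f"precluster-1 merges   {len(self.precluster.merged_into)}",
            f"stage-2 NW alignments {self.stage2.nw_alignments}",
            f"precluster-2 hits     {self.stage2.shortcut_placements}",
            f"stage-2 cases         " + " ".join(
                f"{k}:{v}" for k, v in sorted(self.stage2.case_counts.items())),
            f"HAOTUs                {self.n_haotus}",
            f"LAOTUs                {self.n_laotus}",
            f"total OTUs            {len(self.otus)}",
        ]
        return "\n".join(lines)


def run_tsc(reads: Sequence[Read], config: RunConfig | None = None) -> TscResult:
    """Cluster a read collection into OTUs with the two-stage pipeline."""
    config = config or RunConfig()
    reads = list(reads)
    tags = dereplicate(reads)
    split = split_by_cutoff(tags, config.cutoff)

    # abundance-sorted tags put the whole abundant group first, so the
    # rank of an abundant tag is also its row in the distance set
    dset = sparse_all_pairs(split.abundant, config.kmer, config.alignment,
                            cap=config.cluster.cap)
    pre = precluster_denoise(split.abundant, dset,
                             threshold=config.cluster.precluster_threshold,
                             literal=config.cluster.precluster_literal)
    haotus = hierarchical_cluster(pre.seeds, dset, config.cluster.d,
                                  config.cluster.linkage,
                                  indices=[t.rank for t in pre.seeds])
    attach_precluster_members(haotus, pre, split.abundant)
    otus, s2, _index = run_stage2(split, haotus, config.search,
                                  config.alignment, config.kmer,
                                  pre=pre, trace=config.trace)
    return TscResult(otus=otus, split=split, precluster=pre, dset=dset,
                     stage2=s2, config=config, n_reads=len(reads))


def run_tsc_multi(reads: Sequence[Read], config: RunConfig | None = None,
                  linkages: Sequence[str] = ("cl", "al", "sl"),
                  cutoffs: Sequence[int] | None = None) -> dict[tuple[int, str], TscResult]:
    """Run the pipeline for several linkage modes and cutoffs, sharing the
    dereplication and the pairwise distance sweep within each cutoff.

    Results are identical to independent `run_tsc` calls; only the
    redundant distance computation is shared.
    """
    from dataclasses import replace

    config = config or RunConfig()
    cutoffs = list(cutoffs) if cutoffs is not None else [config.cutoff]
    reads = list(reads)
    tags = dereplicate(reads)
    out: dict[tuple[int, str], TscResult] = {}
    for cutoff in cutoffs:
        split = split_by_cutoff(tags, cutoff)
        dset = sparse_all_pairs(split.abundant, config.kmer, config.alignment,
                                cap=config.cluster.cap)
        pre = precluster_denoise(split.abundant, dset,
                                 threshold=config.cluster.precluster_threshold,
                                 literal=config.cluster.precluster_literal)
        for linkage in linkages:
            cfg = replace(config, cutoff=cutoff,
                          cluster=replace(config.cluster, linkage=linkage))
            haotus = hierarchical_cluster(pre.seeds, dset, cfg.cluster.d,
                                          linkage, indices=[t.rank for t in pre.seeds])
            attach_precluster_members(haotus, pre, split.abundant)
            otus, s2, _ = run_stage2(split, haotus, cfg.search, cfg.alignment,
                                     cfg.kmer, pre=pre, trace=cfg.trace)
            out[(cutoff, linkage)] = TscResult(
                otus=otus, split=split, precluster=pre, dset=dset,
                stage2=s2, config=cfg, n_reads=len(reads))
    return out


def run_tsc_fasta(path: str | Path, config: RunConfig | None = None) -> TscResult:
    config = config or RunConfig()
    return run_tsc(read_fasta(path, allow_ambiguous=config.allow_ambiguous), config)


def write_outputs(result: TscResult, outdir: str | Path,
                  label: str | None = None) -> None:
    """Write the OTU membership list (mothur dialect), representative
    FASTA, per-OTU abundance table, summary, and optional logs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    otus = result.otus
    if label is None:
        label = f"{result.config.cluster.d:g}"

    with open(out / "otus.list", "w") as fh:
        fh.write(label + "\t" + str(len(otus)) + "\t"
                 + "\t".join(",".join(o.read_ids) for o in otus) + "\n")

    with open(out / "representatives.fasta", "w") as fh:
        for o in otus:
            fh.write(f">OTU_{o.id};size={o.total_abundance}\n{o.representative.seq}\n")

    with open(out / "otu_abundance.tsv", "w") as fh:
        fh.write("otu_id\tkind\tn_tags\ttotal_abundance\trepresentative\n")
        for o in otus:
            fh.write(f"OTU_{o.id}\t{o.kind}\t{len(o.members)}\t"
                     f"{o.total_abundance}\t{o.representative.exemplar_id}\n")

    with open(out / "summary.txt", "w") as fh:
        fh.write(result.summary() + "\n")

    with open(out / "precluster.log", "w") as fh:
        by_rank = {t.rank: t for t in result.split.abundant}
        for absorbed, seed in sorted(result.precluster.merged_into.items()):
            fh.write(f"{by_rank[absorbed].exemplar_id}\t{by_rank[seed].exemplar_id}\n")

    if result.config.trace:
        with open(out / "trace.log", "w") as fh:
            fh.write("tag_seq\tcase\totu_id\n")
            for seq, case, oid in result.stage2.trace:
                fh.write(f"{seq}\t{case}\t{oid}\n")


class ValidationError(AssertionError):
    pass


def validate_partition(result: TscResult) -> None:
    """Every input read belongs to exactly one OTU and abundances add up."""
    all_ids: list[str] = []
    for o in result.otus:
        if not o.members:
            raise ValidationError(f"OTU_{o.id} is empty")
        all_ids.extend(o.read_ids)
    if len(all_ids) != result.n_reads:
        raise ValidationError(
            f"OTUs hold {len(all_ids)} reads, input had {result.n_reads}")
    if len(set(all_ids)) != len(all_ids):
        raise ValidationError("a read id appears in more than one OTU")
    total = sum(o.total_abundance for o in result.otus)
    if total != result.n_reads:
        raise ValidationError(
            f"sum of member abundances {total} != read count {result.n_reads}")


def validate_outputs(list_path: str | Path, fasta_path: str | Path) -> int:
    """Check an otus.list file partitions the FASTA read ids exactly once;
    returns the OTU count."""
    with open(list_path) as fh:
        line = fh.readline().rstrip("\n")
    parts = line.split("\t")
    n_otus = int(parts[1])
    cells = parts[2:]
    if len(cells) != n_otus:
        raise ValidationError(f"list says {n_otus} OTUs but has {len(cells)} cells")
    listed: list[str] = []
    for cell in cells:
        ids = [x for x in cell.split(",") if x]
        if not ids:
            raise ValidationError("empty OTU cell in list file")
        listed.extend(ids)
    fasta_ids = [r.id for r in read_fasta(fasta_path, allow_ambiguous=True)]
    if sorted(listed) != sorted(fasta_ids):
        raise ValidationError("list file does not partition the input read ids")
    return n_otus
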