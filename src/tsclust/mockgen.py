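"""Synthetic mock amplicon libraries with known templates and bounded noise.

The generator emulates a clone-library accuracy experiment: K templates
kept mutually distant, skewed (power-law) template abundances, and noise
reads guaranteed to lie within ``max_noise_dist`` NW distance of their
parent template (the analogue of screening a mock library against its
templates at 0.03).  Noise has two components:

* recurrent variants — a small set of abundance-skewed single-substitution
  (configurable) variants per template, modelling PCR early-cycle errors
  and platform hotspots that recur in many reads; and
* a random-substitution/indel tail — per-base errors that make each
  affected read essentially unique, producing the singleton tail that
  dominates unique-tag counts in real amplicon data.

Together these reproduce the characteristic situation where singletons
plus doubletons are ~70-80% of unique tags while per-base error rates
stay at realistic post-denoising levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .derep import Read
from .distances import encode, nw_pair_distance
from .params import AlignmentParams, ParameterError

_BASES = np.array(list("ACGT"))


class FeasibilityError(RuntimeError):
    """Template sampling could not satisfy the distance floor."""


@dataclass(frozen=True)
class MockConfig:
    """Study design of a mock library run.

    ``abundances`` (explicit per-template read counts) overrides the
    power-law model when given.  ``recurrent_subs`` must keep recurrent
    variants inside the noise screen."""

    n_templates: int = 43
    template_length: int = 80
    min_template_dist: float = 0.10
    abundance_exponent: float = 1.5
    abundances: tuple[int, ...] | None = None
    n_reads: int = 50_000
    sub_rate: float = 2.4e-4
    ins_rate: float = 0.0
    del_rate: float = 0.0
    max_noise_dist: float = 0.03
    recurrent_per_template: int = 8
    recurrent_frac: float = 0.06
    recurrent_subs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ParameterError("need at least one template")
        if self.min_template_dist <= self.max_noise_dist:
            raise ParameterError("min_template_dist must exceed max_noise_dist")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r < 1.0:
                raise ParameterError("error rates must lie in [0, 1)")
        if not 0.0 <= self.recurrent_frac < 1.0:
            raise ParameterError("recurrent_frac must lie in [0, 1)")
        if self.recurrent_per_template > 0 and self.recurrent_frac > 0:
            if self.recurrent_subs / self.template_length > self.max_noise_dist:
                raise ParameterError(
                    "recurrent variants would violate the noise screen")
        if self.abundances is not None and len(self.abundances) != self.n_templates:
            raise ParameterError("explicit abundances must list every template")


@dataclass
class MockTruth:
    templates: dict[str, str]      # template id -> sequence
    read_parent: dict[str, str]    # read id -> template id


def _template_id(k: int) -> str:
    return f"T{k + 1:03d}"


def generate_templates(cfg: MockConfig,
                       ap: AlignmentParams | None = None) -> list[str]:
    """K random templates, all pairwise NW distances >= min_template_dist.

    Rejection sampling with a retry budget; reproducible from cfg.seed.
    """
    ap = ap or AlignmentParams()
    rng = np.random.default_rng([cfg.seed % (2**31), 17])
    templates: list[str] = []
    budget = 200 * cfg.n_templates
    while len(templates) < cfg.n_templates:
        if budget <= 0:
            raise FeasibilityError(
                f"could not place {cfg.n_templates} templates at distance "
                f">= {cfg.min_template_dist}; use longer templates or fewer K")
        budget -= 1
        cand = "".join(rng.choice(_BASES, size=cfg.template_length))
        if all(nw_pair_distance(cand, t, ap) >= cfg.min_template_dist
               for t in templates):
            templates.append(cand)
    return templates


def _mutate(codes: np.ndarray, rng: np.random.Generator,
            n_sub: int, n_ins: int, n_del: int) -> np.ndarray:
    out = codes.copy()
    if n_sub:
        pos = rng.choice(out.shape[0], size=min(n_sub, out.shape[0]), replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=pos.shape[0])) % 4
    for _ in range(n_del):
        if out.shape[0] > 1:
            p = int(rng.integers(0, out.shape[0]))
            out = np.delete(out, p)
    for _ in range(n_ins):
        p = int(rng.integers(0, out.shape[0] + 1))
        out = np.insert(out, p, rng.integers(0, 4))
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def generate_reads(templates: list[str], cfg: MockConfig,
                   ap: AlignmentParams | None = None) -> tuple[list[Read], MockTruth]:
    """Draw reads with skewed template abundances and screened noise.

    Every emitted read has NW distance <= max_noise_dist to its parent
    template (reads failing the screen are resampled).  Read order is a
    seeded permutation of the per-template blocks.
    """
    ap = ap or AlignmentParams()
    rng = np.random.default_rng([cfg.seed % (2**31), 29])
    K = len(templates)
    if cfg.abundances is not None:
        counts = np.asarray(cfg.abundances, dtype=np.int64)
    else:
        p = (np.arange(K) + 1.0) ** -cfg.abundance_exponent
        counts = rng.multinomial(cfg.n_reads, p / p.sum())
    tcodes = [encode(t) for t in templates]
    max_subs_pass = int(np.floor(cfg.max_noise_dist * cfg.template_length))

    # recurrent variant library, abundance-skewed within each template
    variants: list[list[np.ndarray]] = []
    for k in range(K):
        vs: list[np.ndarray] = []
        seen = {templates[k]}
        tries = 0
        while len(vs) < cfg.recurrent_per_template and tries < 200:
            tries += 1
            v = _mutate(tcodes[k], rng, cfg.recurrent_subs, 0, 0)
            s = _decode(v)
            if s not in seen:
                seen.add(s)
                vs.append(v)
        variants.append(vs)
    vweights = None
    if cfg.recurrent_per_template > 0:
        w = 1.0 / (np.arange(cfg.recurrent_per_template) + 1.0)
        vweights = w / w.sum()

    seqs: list[str] = []
    parents: list[int] = []
    for k in range(K):
        n_k = int(counts[k])
        if n_k == 0:
            continue
        u = rng.random(n_k)
        n_err = rng.binomial(
            cfg.template_length,
            np.array([cfg.sub_rate, cfg.ins_rate, cfg.del_rate]),
            size=(n_k, 3))
        for r in range(n_k):
            if (vweights is not None and variants[k]
                    and u[r] < cfg.recurrent_frac):
                vi = rng.choice(len(variants[k]), p=vweights[:len(variants[k])]
                                / vweights[:len(variants[k])].sum())
                seqs.append(_decode(variants[k][vi]))
            elif n_err[r].sum() == 0:
                seqs.append(templates[k])
            else:
                ns, ni, nd = (int(x) for x in n_err[r])
                while True:
                    mut = _mutate(tcodes[k], rng, ns, ni, nd)
                    if ni == 0 and nd == 0:
                        if ns <= max_subs_pass:
                            break
                    elif nw_pair_distance(_decode(mut), templates[k], ap) <= cfg.max_noise_dist:
                        break
                    # resample the error draw (screened out)
                    ns = int(rng.binomial(cfg.template_length, cfg.sub_rate))
                    ni = int(rng.binomial(cfg.template_length, cfg.ins_rate))
                    nd = int(rng.binomial(cfg.template_length, cfg.del_rate))
                seqs.append(_decode(mut))
            parents.append(k)

    order = rng.permutation(len(seqs))
    reads = []
    read_parent = {}
    for out_i, src in enumerate(order):
        rid = f"R{out_i + 1:06d}"
        reads.append(Read(id=rid, seq=seqs[src]))
        read_parent[rid] = _template_id(parents[src])
    truth = MockTruth(
        templates={_template_id(k): templates[k] for k in range(K)},
        read_parent=read_parent)
    return reads, truth


def generate_library(cfg: MockConfig,
                     ap: AlignmentParams | None = None) -> tuple[list[Read], MockTruth]:
    """Templates plus reads in one call."""
    templates = generate_templates(cfg, ap)
    return generate_reads(templates, cfg, ap)


def write_mock(reads: list[Read], truth: MockTruth, cfg: MockConfig,
               outdir: str | Path) -> None:
    """Write reads.fasta, templates.fasta, truth.tsv and a flat manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reads.fasta", "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.seq}\n")
    with open(out / "templates.fasta", "w") as fh:
        for tid, seq in truth.templates.items():
            fh.write(f">{tid}\n{seq}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("read_id\ttemplate_id\n")
        for rid, tid in truth.read_parent.items():
            fh.write(f"{rid}\t{tid}\n")
    with open(out / "manifest.txt", "w") as fh:
        for key, val in vars(cfg).items():
            fh.write(f"{key}={val}\n")
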