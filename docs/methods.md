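# Methods

## Model and rationale

Amplicon libraries have a characteristic unique-sequence abundance
profile: a small abundant core and a long rare tail (singletons plus
doubletons are roughly 70–80% of unique tags), and the tail is enriched
for PCR and sequencing artifacts that sit close to an abundant parent
sequence. `tsclust` exploits this: only the abundant core is clustered
with the expensive, accurate hierarchical procedure, and the tail is
attached afterwards by a greedy nearest-OTU search. Both stages use the
same pairwise Needleman–Wunsch (NW) distance, so every read's OTU
membership is still justified by a pairwise alignment; the asymmetry is
purely in which comparisons are evaluated.

The package assumes its input is a single orientation-normalized
amplicon region, already demultiplexed, quality-filtered, denoised and
chimera-screened. It is not a denoiser: an artifact far from its parent
cannot be recognized as such here.

## Distances

**Alignment scoring.** Affine-gap global alignment (Gotoh three-state
DP): match +1, mismatch −1, gap open −10, gap extend −1; an internal
gap run of length L costs g + e·(L−1). End-gap columns are charged like
extensions, without an open penalty: e per column on Illumina, 0 in 454
mode (which also zeroes internal extensions, so any internal run costs
g). This follows the platform error models: Illumina errors are
substitutions, so gaps should stay expensive column-by-column, while
454 homopolymer errors produce runs that should be priced (and counted)
once. The `-x` flag does not alter scoring; it trims terminal gap
columns before the distance is counted. We considered making `-x` free
the end gaps in scoring as well, but the shipped defaults pair `-x`
with the −1-per-end-gap-column Illumina model, so trimming is a
distance-side convention only.

**Distance.** d = (substitution columns + gap differences) / alignment
length after optional end trimming, where gap differences are gap
columns (Illumina) or maximal gap runs (454); `--gap-count-mode`
overrides the platform default. A degenerate alignment whose trimmed
span is empty scores 1.0. The denominator is the trimmed alignment
length — the convention of the sparse-pairwise-distance lineage this
design builds on.

**Determinism.** Traceback prefers diagonal, then a gap in the second
sequence, then the first; at termination the corner is preferred over
trailing-gap variants. Ties in scores therefore resolve identically on
every run.

**k-word prescreen.** d_k = 1 − shared k-words / (min length − k + 1),
k = 6, computed on sorted k-word multisets. Pairs with d_k > 0.5 are
never aligned; at the 0.03–0.10 distances that matter here the k-word
distance of a qualifying pair is far below 0.5, so the prescreen is a
safe reject of hopeless pairs, not a tunable approximation. Words
containing ambiguity codes are dropped from the multiset (ambiguous
bases also never match during alignment; inputs containing them are
rejected unless `--allow-ambiguous`).

**Sparse storage.** Only distances ≤ cap (default 0.10) are stored;
absent pairs mean "above cap". The cap bounds which clustering
thresholds are usable (0.03/0.05/0.10 all fit) and is checked against
`-d` at run time. The numba kernels are serial; `-s/--threads` is
accepted for interface compatibility and recorded, but results never
depend on it because all merge decisions happen in one fixed order.

## Stage 1

**Precluster (denoising).** One sequential pass over the abundant tags
in abundance order: the current seed absorbs every still-unabsorbed
lower-ranked tag within 0.02; absorbed tags are never revisited.
Exactly one round — the abundant group has already shed most of the
noise tail, and a second round would only re-chain seeds the first pass
deliberately separated. By default a seed's weight grows by the
absorbed tag's full abundance, which conserves read counts through to
the OTU tables; `--precluster-literal` increments by 1 instead
(the historical convention). Memberships are identical in both modes —
only representative weighting differs.

**Agglomeration.** Single linkage is computed as connected components
of stored edges ≤ d (union-find). Complete and average linkage run a
greedy dense agglomeration — merge the closest pair while the linkage
distance ≤ d, Lance–Williams updates (max; size-weighted mean, which
equals the mean over all between-cluster tag pairs) — inside each
single-linkage component, with missing pairs valued cap + 1e−6. The
decomposition is exact: any CL/AL merge needs its between-cluster mean
or max ≤ d, impossible across components where every pair exceeds d.
Equal-distance merges take the lexicographically smallest index pair.

## Stage 2

Rare tags are processed in abundance order; each placed tag immediately
becomes a search target for later tags (the LAOTU-merging cases depend
on this).

**Shortcut (precluster 2).** The tag is compared base-by-base, without
alignment, against current OTU representatives in OTU-creation order;
unequal lengths compare over the shorter length with the difference
added as mismatches and the longer length as denominator. A direct
distance strictly below d places the tag at zero alignment cost. The
candidate set is representatives only: that keeps the shortcut linear
and biases it toward abundant parents, which is its denoising purpose.
The direct distance upper-bounds the NW distance, so a shortcut
placement always satisfies the NW threshold too (property-tested).

**Greedy search.** Remaining tags are ranked against placed tags by
k-word distance (candidates beyond f_max = 0.5 excluded); NW distances
are evaluated in batches of `-n` (10), continuing while a batch
contains at least one hit (NW ≤ d, non-strict) and stopping after the
first empty batch. The accumulated hits decide: (1) none → new LAOTU;
(2) one OTU → join it; (3) ≥ 2 HAOTUs → join the HAOTU of the most
abundant hit tag, never merging HAOTUs; (4) ≥ 2 LAOTUs → merge them
(the earliest id survives); (5) both kinds → fold all hit LAOTUs into
the HAOTU of the most abundant hit tag. Ties on hit-tag abundance break
toward the earlier OTU id. Ranking against all placed tags (not only
representatives) is the default; `rank_targets="representatives"`
trades a little sensitivity for memory. The batched stopping rule is a
heuristic: on adversarial inputs where k-word order is a poor proxy for
NW distance a later would-be hit can be missed (the test suite
constructs exactly such a case to document the behaviour).

## Mock-library generator

The generator emulates clone-library accuracy experiments in which
reads from K known templates are screened to lie within a fixed NW
distance of their template, so the correct OTU count is K by
construction. Defaults: K = 43 templates of length 80 (V6-like), all
pairwise NW ≥ 0.10 (rejection sampling, seeded, with a retry budget),
power-law template abundances with exponent 1.5, 50,000 reads,
noise screen at 0.03.

Noise has two parts, and the split is the point. Recurrent variants —
8 per template, single-substitution, abundance-skewed, ~6% of reads —
model PCR early-cycle errors and platform hotspots that recur across
reads and produce the multi-copy error tags real libraries contain.
Independent per-base errors (substitution rate 2.4e−4 by default;
indels available for 454-flavoured fixtures) produce the
mostly-singleton tail. With these defaults the singleton+doubleton
fraction of unique tags measures ≈ 74–77% across seeds, matching the
characteristic 70–80% band, at an error rate plausible for
post-denoising data. Raising rates (e.g. substitutions 4e−3 with
two-substitution recurrent variants and a 0.05 screen) gives the
heavier-noise regime used to study cutoff behaviour.

Because min template distance (0.10) exceeds twice the noise radius
(0.03), no read can sit within the threshold of a non-parent template,
so recovery experiments have an unambiguous ground truth; this margin
is asserted empirically in the tests. Reads failing the screen are
resampled; substitution-only reads are screened by count (sufficient
bound), indel reads by actual NW distance.

**What the mock does not model:** chimeras, quality scores, length
variation between templates, reverse-complement reads, and
context-dependent error spectra beyond the hotspot approximation.
Passing the recovery experiments shows the pipeline's clustering logic
is correct under the stated noise geometry — not that real communities
have 43 taxa or that denoising can be skipped.

## Problem sizes and numerical choices

The shipped experiments use 50,000-read libraries for recovery and
10,000-read libraries for the cutoff-convergence study; both complete
in well under a minute after JIT warm-up, and the sizes are large
enough that every pipeline path (precluster absorption, all five
stage-2 cases across regimes, sparse-matrix retry growth) is exercised.
Clustering-oracle checks run 200 random instances of ≤ 50 seeds against
an independent dense implementation; alignment scores are verified
exhaustively for all sequence pairs of length ≤ 6 over a two-letter
alphabet under four scoring conventions.

Floating-point distances are compared with exact operators; distances
are ratios of small integers, and the missing-pair constant (cap +
1e−6) keeps absent pairs strictly above any usable threshold without
overflowing comparisons.

## Known limitations

* Stage-2 results depend on processing order (abundance-descending,
  deterministic); a different order can place borderline tags
  differently. This is inherent to the greedy design.
* The batched search can miss hits when k-word ranking misorders
  candidates (documented above).
* OTU ids are creation-ordered, not stable across parameter changes.
* Memory in stage 2 grows with placed tags (k-word store); the
  representatives-only mode is the escape hatch for extreme datasets.
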