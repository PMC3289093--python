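# Methods

This note records the models, parameter choices and numerical conventions
behind `curdseq`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Synthetic data model

The generator emulates a two-condition, one-library-per-condition curd
transcriptome comparison:

- **Transcripts.** Random iid sequences with uniform lengths in
  [300, 2000] bp and a configurable GC target (default 0.4, plant-like).
  Real transcripts have codon structure, UTR composition bias and gene
  families; none of that is modeled, which makes assembly *easier* than
  reality (fewer repeats), so assembly tests demonstrate contract
  correctness, not hard-genome performance.
- **Counts.** Per gene and library, read counts are Poisson with mean
  proportional to the gene's expression level times the library depth —
  the standard model for digital expression counts from a single library
  per condition. Base abundances are log-normal (σ = 1); a designed
  fraction of genes carries a true fold change drawn from the design's
  fold set, oriented test/reference. Defaults: 5% up + 5% down at folds
  {3, 5, 10}, expected depth 20,000 reads/library at desk scale (the
  emulated study is ~15 million; every statistic here scales with depth,
  so desk-scale runs keep test time in seconds). Overdispersion
  (negative-binomial) is deliberately not the default: with no biological
  replicates there is nothing to estimate it from, and the Poisson
  assumption is exactly what the chi-square calibration of the test
  statistic relies on.
- **Reads.** 86 bp, unstranded (strand 50/50), start positions uniform
  over the transcript; iid substitution errors (default 0.5%), no indels,
  no quality-dependent error profile. A configurable fraction of expected
  depth (default 5%) is drawn from rRNA contaminant records; a fraction of
  reads (default 5%) carries 3′ adaptor read-through: the insert is
  shorter than the read length and the read is padded with the adaptor
  sequence. Qualities are constant high with an optional low-quality 3′
  tail so quality trimming is exercised. Because totals are Poisson sums,
  the realized library size fluctuates around the design depth; the truth
  ledger records every emitted read, and conservation is asserted against
  the ledger rather than the nominal depth.
- **Truth ledger.** Per gene: expected counts in both conditions, true
  fold (flagged `ref_zero` when the reference mean is 0), DE flag (up iff
  fold ≥ 3, down iff ≤ 1/3). Per read: origin sequence, 0-based start,
  strand, error count, adaptor status and insert length. Recovery tests
  compare pipeline output against this ledger exactly wherever the
  simulation is error-free.

One master seed drives the whole generation; per-stage generators derive
from it by seed-sequence spawning, so outputs are byte-identical across
runs with the same seed and parameters.

## Read QC

Adaptor trimming finds an exact seed match (first 10 adaptor bases) in the
read and extends to the read's 3′ end allowing 10% mismatches; the match
must run to the end of the read (read-through geometry). Read-through
stubs shorter than the seed are undetectable by construction — a
limitation shared by every seed-based trimmer — so the recovery test
defines its expectation from the ledger's insert lengths. Quality trimming
is a plain 3′ scan at phred ≥ 20 (the trimming rule is a documented
package choice); reads shorter than 30 bp after trimming are discarded.

Contamination screening removes a read iff its full length matches some
position on either strand of an rRNA record with at most 2 substitutions
(N never matches). Matching is k-mer pigeonhole seeding: the read is split
into `max_mismatch + 1` chunks; any within-budget placement leaves at
least one chunk exact, so an exact 12-mer index over the references finds
every candidate, which is then verified by direct Hamming counting. Reads
too short to carry `max_mismatch + 1` seeds fall back to a brute scan.
This is contract-equivalent, at desk scale, to short-read alignment with a
mismatch cap.

## Assembly

The overlap assembler is greedy overlap-layout-consensus: repeatedly merge
the pair of contigs with the highest-scoring dovetail or containment
overlap (score = matching bases; ties break on the lexicographically
smallest member id) until no overlap of ≥ 40 bp at ≥ 97% identity remains,
with candidate offsets proposed by shared k-mers (k = min(16,
min_overlap/2)). Consensus is per-column majority vote over all stacked
input bases, ties to the lexicographically smallest base. Both thresholds
are configurable; the defaults are package choices (the emulated protocol
does not publish its assembler's parameters) and sit where Sanger-quality
error rates (< 1–2%) still merge while unrelated sequences do not.

The de Bruijn assembler counts canonical 31-mers, drops singletons when
mean k-mer coverage ≥ 10 (error k-mers are almost all singletons at that
coverage; below it, dropping singletons would fragment real sequence),
prunes dead-end tips shorter than 2k, and emits maximal unbranched paths
≥ 100 bp, reported once in canonical orientation. There is no bubble
popping, scaffolding or paired-end support; transcripts sharing exact
31-mers (isoforms, repeats) will produce branched graphs and fragmented
contigs, which mirrors the behaviour of any unpaired short-read assembler.

End effects: with uniformly random read starts, a transcript's terminal
k-mer is covered only by reads starting exactly at the end, so full
end-to-end recovery is only guaranteed under tiling coverage; the
assembly round-trip tests tile deliberately, and the random-coverage test
asserts 95% recovery instead.

Meta-assembly reruns the same greedy merge over the union of EST-unigenes
and de novo contigs, then renumbers `PP000001…` by decreasing length
(ties by sequence), keeping a total id map from every input unigene to its
final id. Provenance is `est`, `denovo`, or `merged` when members of both
kinds coalesce.

Read-to-unigene alignment reuses the pigeonhole matcher; each read reports
every equally-best (fewest-mismatch) placement across unigenes and both
strands, with coordinates 0-based on the forward unigene.

## Quantification

A read contributes at most 1 count to exactly one unigene. The default
multimapping policy discards reads with tied best placements
(conservative); `best-unique` instead picks one tied placement uniformly
at random with a seeded generator. Library size is the number of reads
assigned to the final unigene set in that library — a mapped-read
denominator, so rRNA-screened and unassigned reads do not dilute RPKM.
RPKM = count × 10⁹ / (library_size × length); it is linear in count and
invariant under common scaling of counts and library sizes.

## Differential expression

With f = Σx_i/ΣN_i, R = Σ_{x_i>0} x_i ln(x_i/(N_i f)) (natural log,
zero-count terms contribute 0, R = 0 when Σx = 0). R equals the Poisson
log-likelihood ratio between per-library free rates and a shared rate; the
test suite verifies 2R against an independent numeric likelihood
maximization to 1e-8 on random count vectors. p-values default to the
upper tail of χ²(m−1) at 2R — asymptotically exact under the Poisson
model — with a Poisson parametric bootstrap (add-one p-value convention)
for low counts; the package reports p to machine precision. Genes with
zero counts in every library are excluded from testing and from the BH
batch (they carry no information and would only dilute the FDR
adjustment). BH adjustment is delegated to statsmodels and checked in the
tests against a brute-force min-over-tails implementation of the step-up
definition.

Calls: up iff q ≤ 0.01 and RPKM fold ≥ 3; down iff q ≤ 0.01 and fold ≤
1/3. Fold is computed on RPKM in test/reference orientation; the
zero-reference convention (ratio = test RPKM when reference is 0; 1 when
both are 0) matches the layout of published expression tables and is
equivalent to a unit denominator. Full precision is kept internally;
rounding happens only in reports.

A property worth stating explicitly: RPKM fold changes are *compositional*.
If a sizable share of total expression rises in one condition, the mapped-
read denominator of that library grows and every observed fold shifts
toward the reference by the library-size ratio. With 10% of genes planted
up-regulated 10-fold one-sidedly, the test library roughly doubles to
triples in size and observed folds compress from 10 to ~3.5–5; under the
symmetric default design (5% up + 5% down) the shift is mild and fold-10
up-planted genes are recovered in full, while down-planted genes (whose
observed folds sit near 1/3 times the size ratio) are all detected as
significant but can straddle the fold filter. This is a property of the
normalization, not of the test statistic.

## Target overlap

Homolog assignment is one-directional best hit: candidate reference genes
must share an exact 11-mer with the unigene (either strand) and are scored
by local alignment (match +2, mismatch −3, gap open −5, extend −2, via
Biopython's pairwise aligner); the best-scoring hit is kept when score ≥ 50
and the e-value-like quantity K·m·n·exp(−λS) (λ = 0.5, K = 0.1 — generic
Karlin–Altschul-style scaling, documented as approximate since only the
threshold matters) is ≤ 1e-6. Reciprocal-best filtering is deliberately
not used, matching one-directional "top hit" tables.

Overlap accounting intersects disjoint up/down DE unigene sets with the
target catalogue through the homolog map and reports all four up/down ×
light/dark intersections explicitly; a target labeled `both` counts toward
both decompositions. Category tallies deduplicate input ids, count a gene
once per category it belongs to, and route unannotated genes to
`unclassified`.

## Pigments

Extract concentrations come from the two-coefficient linear system given
in the README; per-fresh-weight scaling is volume/mass (×20 at the default
1 mL / 50 mg geometry) and is applied explicitly. A 1 cm path length is
assumed; no dilution correction. Readings implying negative concentrations
are returned flagged invalid rather than raised, since they are data
(instrument noise at low signal), not programming errors. The generator's
inverse operation solves the same 2×2 system in reverse and rejects
infeasible concentration pairs; round-trip identity holds to 1e-6
relative, which the tests assert, including at the green-curd reference
point (total 344.4 μg/g FW, a/b = 3.43). No raw OD readings are published
for the emulated study, so pigment verification is round-trip and
property-based by necessity.

## Pipeline

`run_all` executes simulate → trim → rRNA screen → EST screen/assembly →
read alignment → de novo assembly → meta-assembly → counting/RPKM → DE →
(optional) target overlap, writing per-stage artifacts and a JSON + text
report that restates every parameter. One master seed spawns per-stage
seeds; stage outputs are pure functions of inputs, config and seeds, and
the determinism test asserts byte-identical artifacts across reruns.
Configuration is a YAML-serializable dataclass with exhaustive validation
(`validate_config` returns one finding per violated constraint).

## Problem sizes

Tests run at desk scale by design: tens of genes and thousands of reads
for read-level stages, 2,000 genes at 100,000 expected counts per library
for the count-level DE checks, 50 transcripts for assembly round trips.
These sizes keep the full suite under a minute while leaving every
statistical check with comfortable Monte-Carlo margins.

## Known limitations

- No indels anywhere: the matcher is substitution-only, and the
  assemblers assume gap-free overlaps.
- No paired-end, stranded, or quality-aware processing.
- The overlap assembler is O(pairs × overlap length) and meant for
  thousands of inputs, not millions.
- Homolog e-values are approximate by construction; use the score
  threshold for anything quantitative.
- One library per condition: the test inherits the Poisson single-library
  framework and cannot see biological variance; q-values control the FDR
  under that model only.
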