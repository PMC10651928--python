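# Methods

This note documents the models, rules and numerical choices behind `pansv`,
and what the synthetic generator does and does not emulate.

## SV representation

All coordinates are 0-based half-open so that `length = end − start` holds
everywhere the overlap-ratio formulas need it. Four SV types are handled:
presence (insertion relative to the reference), absence (deletion),
inversion and translocation. Presence SVs are anchored by a 1–2 bp point
interval on the reference plus an `sv_length` attribute for the inserted
length, because inserted sequence has no reference extent; the 5 bp anchor
rule is applied to start positions. A translocation is represented by its
source-side reference interval.

## Merge rules

Two pairwise similarity rules drive both the within-accession consensus and
the cross-accession merge:

- **union overlap ratio** (absence, inversion, translocation):
  `|a ∩ b| / |a ∪ b|`, where the denominator is the non-redundant length
  covered by the two intervals. Symmetric, 1 iff identical, 0 across
  chromosomes.
- **presence rule**: `min(ℓ₁,ℓ₂)/max(ℓ₁,ℓ₂) > t` AND
  `|start₁ − start₂| < 5 bp`.

The threshold `t = 0.90` is compared strictly (`>`); the operator is
configurable (`strict_threshold`) because the source material uses both
"exceeded 90%" and "≥ 90%" phrasings, and "exceeded" is the more precise
formula statement.

**Consensus.** A candidate SV in one accession requires one call from each
of the three configured callers such that all three pairwise similarities
pass — the strictest symmetric reading of "overlap in all three callsets".
Triples are assigned greedily by the best minimum pairwise ratio, and each
call supports at most one candidate, keeping counts conservative. Inversion
and translocation candidates are exactly the calls of the configurable
primary caller (default name `syri-like`), reflecting that only a
synteny-based caller is trusted for rearrangements.

**Cross-accession merging** is single-linkage clustering under the
type-appropriate predicate. Single linkage matches a repeated pairwise merge
procedure without re-checking; its known non-transitivity is surfaced: each
merged SV records `min_pair_ratio`, the smallest pairwise similarity inside
the cluster. The representative is the member with the longest interval
(ties: smallest start) — a deterministic invented convention recorded per
cluster. Inputs are canonically sorted before clustering, so the output is
independent of input order; the operation is idempotent.

## Context annotation

Each SV receives exactly one label with precedence
exon > intron > promoter > downstream flank > intergenic, so labels
partition the SV set and counts sum exactly. Gene-body-first precedence was
chosen because an exonic hit has the most direct coding consequence; the
order is configurable in principle but fixed by default. Flanks are ±5 kb
measured from the coding span; the upstream (5′, strand-aware) flank is the
promoter, the 3′ flank is reported separately as `downstream_flank`. An SV
spanning several genes takes the gene with the largest overlap (ties:
leftmost). Overlap means ≥ 1 bp intersection.

A PAV counts as TE-derived when ≥ 50% of its reference interval is covered
by TE annotation (absence), or when its inserted sequence carries a TE
annotation (presence, via `inserted_te_class`). The 50% threshold is a
package choice (`te_overlap_frac`) — the qualitative criterion "formed by
TEs" needs an operational cutoff.

## Hotspots

Every SV contributes two breakpoints (start and end; a single anchor for
insertions). Breakpoints are counted in 400 kb windows sliding by 200 kb;
an interior breakpoint therefore lands in exactly two windows. Terminal
windows are truncated and keep raw (un-normalized) counts. Exactly
`ceil(0.10 × #windows)` windows are selected by descending count with a
positional tie-break for reproducibility, and overlapping or abutting
selected windows merge genome-wide into hotspot regions.

## Pan-gene clusters and loci

Categories over `n = 13` accessions: core (13), soft-core (11–12),
dispensable (2–10), specific (1); a cluster is present in an accession iff
it holds ≥ 1 gene there, regardless of copy number. Percentages are rounded
half-up to two decimals. Saturation curves use 100 seeded random
genome-addition orders by default (13! is infeasible; exhaustive
enumeration is practical up to ~8 accessions and used in tests); per order,
the pan curve is non-decreasing and the core curve non-increasing by
construction.

Pan-gene loci are built stepwise from the base accession: a new gene joins
the locus of its collinear partner, or founds a new locus when it has no
partner in the current table. Two conflict rules are package choices: a
gene collinear to several loci joins the earliest-founded one (stable), and
a second gene of the same accession mapping to an already-filled locus
founds a new locus, preserving the one-gene-per-accession-per-locus shape.

## gCNV and expression

Copy number of a gene in an accession is the number of distinct loci among
alignment hits passing identity > 0.90 and coverage > 0.90; hits with > 50%
reciprocal overlap collapse into one locus (the locus boundary definition is
a package choice). Zero copies encodes gene deletion. Near-identical
pan-genes (identity and coverage both > 0.90) are deduplicated to one
representative per connected component before CNV calling.

Correlation is Pearson's r with the two-sided p-value from the
t-transformation at n − 2 degrees of freedom, flagged at p < 0.05 and
|r| > 0.5, with no multiple-testing correction (matching the raw-threshold
filter; a BH-adjusted view can be derived from the emitted p-values).
Constant copy-number rows have undefined r and are never flagged. Leaf
correlations use all 13 accessions; peel and flesh use the five
fruit-sampled accessions (GS, OR, SD, FJ, GA), where the effective |r|
threshold implied by p < 0.05 at n = 5 is ≈ 0.88.

## Synthetic generator

The generator plants ground truth at desk scale while keeping the study's
structure:

- **Genome**: 3 chromosomes, 30 Mb total. Chosen once as the smallest
  genome giving ~150 hotspot windows and hundreds of SV events.
- **SV events**: per-Mb rates (presence 4, absence 4, translocation 1,
  inversion 0.1 per Mb) preserve the published ordering PAV ≫ translocation
  ≫ inversion at reduced absolute scale. PAV lengths are lognormal
  (median 600 bp, clipped to 50–20,000 bp); rearrangements are larger.
  Same-type events are placed without overlap (60 bp pad), so distinct
  truth events can never satisfy a merge predicate and the truth frequency
  spectrum is exactly recoverable under perfect callers.
- **Sharing**: accession frequency `f ∈ 1..13` with `P(f) ∝ f^−1.5`, which
  reproduces the "most SVs are private or nearly so" spectrum shape.
- **Callers**: three independent callers with sensitivity 0.95, 0.2 false
  positives per Mb (uniform, never mapped to truth), breakpoint jitter
  uniform within ±2% of event length, insertion anchors jittered ±2 bp and
  inserted lengths by ±2%. These jitters keep any two observations of one
  event above the 0.90 predicates (worst case (L−2j)/(L+2j) ≈ 0.923 at
  j = 0.02 L), so consensus recall is governed by sensitivity alone
  (≈ s³ for three independent callers).
- **TE status**: each PAV is planted TE-derived with probability 0.7131
  (LTR/Gypsy 0.4327 of all PAVs); the annotation generator emits TE
  intervals covering planted absence events and avoids non-TE ones, plus
  background TE to a 40% genome fraction.
- **Clusters**: category proportions equal the published proportions;
  per-present-accession gene counts are 1 + Poisson with means derived from
  the published genes/cluster ratios.
- **CNV/expression**: copy numbers are drawn i.i.d. from
  {0: 0.02, 1: 0.70, 2: 0.18, 3: 0.10}; planted genes (default half of 200)
  follow `expr = a + b·CN + N(0, σ²)` with `b = σρ/(sd(CN)·√(1−ρ²))` for a
  population correlation ρ = 0.8; other genes are independent of CN.
  Expression is clipped at zero (the baseline of 10 with σ = 1 makes
  clipping negligible).
- **Pan-gene loci**: 300 loci present per accession with probability 0.9
  and consistent 1:1 anchors for all co-present pairs.

**What the generator does not emulate**: sequence content (no FASTA),
alignment artefacts, caller-specific error modes (systematic biases,
breakpoint-type confusion), linked/overlapping SVs, nested TEs inside
genes, copy-number–dependent expression saturation, and population
structure among accessions. Passing tests therefore demonstrate the
correctness of the merge/count/correlation logic under the stated noise
model, not caller performance on real genomes.

## Numerical choices and degenerate inputs

- Ratio thresholds are compared strictly; ties at the hotspot decile
  boundary break by (chrom, start); `k = ceil(top_frac × #windows)` is
  fixed.
- Empty callsets are legal (a caller may see nothing); empty SV input gives
  all-zero window counts; `select_hotspots` on zero windows is an error.
- Constant copy-number rows yield `r = NaN`, `p = 1`, never flagged, with
  the reason logged.
- Percentages use decimal half-up rounding, not binary float rounding.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence tests run 1,000 random ≤ 50-call instances; recall tests
use 2,000 planted events in a single 40 Mb accession; the null
CNV-expression test uses 10,000 genes at 13 accessions against a
200,000-draw Monte-Carlo null; saturation tests use 100 random 50-cluster
matrices with all 120 permutations of 5 accessions. The acceptance script
runs the full default study conditions (13 accessions, 30 Mb genome). These
sizes were chosen to make sampling error small relative to the asserted
tolerances while keeping the suite quick.
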