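# Methods

## The validation model

A germline CNV carried by one monozygotic twin should be carried by the
other twin and by at least one parent. Ignoring de novo events — a
negligible fraction of the total CNV burden — any call violating this rule
is a caller artifact: a false positive in the twin that carries it, or a
false negative in the relatives that lack it. All metrics in this package
are built on that single idea; no external truth set is needed.

Two simplifying assumptions are inherited from the study design: twins are
treated as genetically identical (somatic and de novo differences are
ignored), and a call found in a parent is treated as transmitted rather
than independently recurrent.

## Call representation and normalization

Calls are intervals with a binary status, GAIN or LOSS, relative to the
diploid state; the numeric copy number is deliberately discarded so that
callers with different copy-number conventions remain comparable.
Coordinates are 0-based half-open everywhere internally (a reader flag
converts 1-based inclusive input); chromosome names are compared after
stripping an optional `chr` prefix, since callers emit mixed dialects.

Before any comparison, call sets are normalized with `merge_adjacent`:
within each (chromosome, status) group, calls separated by **less than**
5 kb (strict inequality; a gap of exactly 5 000 bp stays split) are fused
into their spanning interval, and overlapping same-status calls are fused
likewise (overlap being a stronger adjacency than a small gap).
Opposite-status calls are never merged, even when overlapping — keeping
both loses no information. The operation is idempotent and
order-independent. `merged_fraction` reports the share of calls touched by
at least one merge, which diagnoses fragmentation-prone callers.

## Reciprocal-overlap matching

For calls A and B, RO(A,B) = (overlap/|A|, overlap/|B|). A match at
threshold *t* requires the same chromosome, the same status, and
min(RO) ≥ *t*; the comparison is inclusive to avoid floating-point knife
edges exactly at the threshold. The working default is *t* = 0.70.
Status-aware matching is the conservative choice: a gain and a loss over
the same interval are different events.

Matching multiplicity is many-to-one: a call counts as shared as soon as
*any* counterpart matches. No one-to-one assignment is attempted, because
fragmentation makes assignment brittle and the symmetric counting in the
rate formulas compensates.

## Inherited CNV rate

Per quartet, with I₁ (I₂) the twin-1 (twin-2) calls matched in the co-twin
and in the union of the two parents' call sets:

    rate = (|I₁| + |I₂|) / (N₁ + N₂)  =  2·shared / (N₁ + N₂),

where shared = (|I₁|+|I₂|)/2. "At least one parent" is evaluated against
the parents' pooled call set, not each parent separately. When N₁+N₂ = 0
the rate is undefined and reported as missing, never as 0. All counts are
post-normalization. The rate is non-increasing in the RO threshold.

## Familial-relationship classification

Per family the pair table holds one twin pair and two child–parent pairs
(twin 1 against each parent; with identical twins the choice of twin is
immaterial and configurable), plus one random cross-family pair per family
drawn uniformly without replacement from all individuals (seeded). Each
pair's sharing rate is the symmetric
(|shared(a,b)| + |shared(b,a)|)/(|a|+|b|).

The 1-D rates are clustered with k-means (k = 3, 10 seeded restarts, best
within-cluster sum of squares kept; the scikit-learn implementation).
Clusters map to labels by rank of their mean rate — highest → twin,
middle → parent–child, lowest → unrelated. If every rate is identical the
clustering is flagged degenerate rather than trusted. The score is the
support-weighted mean of per-class F1 = 2PR/(P+R), computed in-package
from the confusion matrix (a class absent from both vectors contributes 0)
and cross-checked against scikit-learn in the tests.

## Cross-caller agreement

RO matching is not transitive, so "the same CNV seen by several tools" is
defined as a connected component of the match graph over one sample's
calls from all sources. This closure is deterministic, order- and
relabeling-invariant, and never splits a matched pair. A component counts
once in the Venn cell indexed by its source subset, regardless of how many
calls one tool contributed to it.

Mendelian-filtered Venn cells need an "inherited subset" per sample, which
is only defined for twins; filtered cells — and the raw baseline used for
the per-cell loss ratio 1−B/A — are therefore averaged over twin samples,
while the plain unfiltered table averages over all samples.

Pairwise union/intersection call sets emit one call per kept component
(union: all components; intersection: components containing both sources),
spanning the component's members. On normalized inputs, self-union is the
identity. Emitted combined sets feed straight back into the inherited-rate
machinery.

## Breakpoint sensitivity

`ro_sweep` evaluates the family-averaged inherited rate on a strictly
increasing threshold grid (default 0.1–0.9 in steps of 0.1) and summarizes
the curve by the mean of successive finite differences — on a uniform grid
this equals the endpoint slope, so the distinction between the two
conventions never matters for the default grid. Exact-breakpoint callers
produce flat curves (slope 0) whatever their false-positive load, because
an exact match survives every threshold; breakpoint jitter tilts the curve
downward. Families with no twin calls are skipped as undefined at every
threshold.

## Feature association

Calls are annotated with size (bp), GC content — (G+C)/(A+C+G+T) over the
call's reference span, ambiguous bases excluded from the denominator —
and two distances counted in intervening bases: to the nearer chromosome
end (used as the telomere proxy, since true telomere coordinates are
assembly-dependent) and to the centromere interval (0 when overlapping;
the interval is taken from the `acen` rows of a UCSC-style cytoband
table). Concordance (membership in the Mendelian-consistent subset) is
regressed on the four features with a multivariate logistic model fit by
Newton/IRLS (tolerance 1e−8, ≤100 iterations, via statsmodels), with Wald
p-values per coefficient and a Bonferroni-corrected significance threshold
α/4 (default 0.01/4 = 0.0025). Features are standardized by default for
numerical stability — this rescales slopes but provably leaves Wald
p-values unchanged (verified in the tests). Perfect separation is reported
as a non-converged result rather than an exception; a rank-deficient
design raises an error naming the collinear features.

## The simulator

The generator emulates the twin-quartet study design end to end:

- **Genome**: five chromosomes totalling 200 Mb — large enough that
  chance RO matches between unrelated calls are negligible (<0.2% per
  call), small enough that every analysis runs in seconds.
- **Parental genomes**: 60 private CNVs per parent plus independent draws
  (carrier frequency 0.25) from a 40-CNV population pool shared across
  families; the pool is what gives unrelated individuals a small nonzero
  sharing rate, as real populations do. Sizes are log-normal (median
  8 kb, σ_log = 0.9, floor 1 kb), matching the >1 kb convention and the
  kb-to-hundreds-of-kb range real callers report; 40% of CNVs are gains.
  Within a genome, CNVs are placed with a minimum separation of 10 kb
  (twice the merge gap) so normalization can never fuse two distinct true
  CNVs.
- **Transmission**: each parental CNV reaches the child independently
  with probability 0.5; twin 2 is an exact copy of twin 1. De novo CNVs
  are not simulated, so every true twin call is inherited by
  construction and all Mendelian inconsistency in observed data is caller
  error.
- **Virtual callers**: a profile misses each true CNV with probability
  `fn_prob`, jitters surviving breakpoints with N(0, `jitter_sd`),
  rescales sizes by `size_bias` about the midpoint, splits a survivor
  into two fragments with an internal sub-5-kb gap with probability
  `frag_prob` (healable by normalization), and adds Poisson(`fp_rate`)
  uniformly placed false calls. The four default profiles span the
  behaviours the metrics are designed to expose: clean read-depth with
  mild size overestimation, clean hybrid, permissive paired-end (many
  FPs, 400 bp jitter), and heavily fragmenting.
- **Determinism**: one seed drives a `SeedSequence` tree covering truth
  generation and every caller's observations; identical configs reproduce
  byte-identical output.

Every emitted call carries truth labels (true/false positive, originating
CNV, inherited flag), enabling exact cross-checks between the simulator's
ground truth and the pipeline's inferences.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: locus-dependent error rates (e.g. around
segmental duplications), correlated errors between callers run on the
same alignments, nested or overlapping true CNVs within a genome, sex
chromosomes and ploidy effects, and de novo events. Results on synthetic
studies validate the *metrics*, not any particular caller.

### Closed-form error-model expectation

For a pure FN/FP profile (miss probability β, Poisson-mean F false calls
per sample, no jitter/fragmentation, no population pool),
`expected_inherited_rate` computes the exact expected per-family rate:
the twins share T ~ Binomial(2n, τ) true CNVs; each is seen by neither,
one, or both twins with probabilities β², 2β(1−β), (1−β)², and a
both-twin CNV is validated when its origin parent sees it (probability
1−β). With m one-twin and k both-twin CNVs and P ~ Poisson(2F) pooled
false calls, E[rate] = E[2k(1−β)/(m+2k+P)], summed exactly over the
discrete grid and conditioned on a nonzero denominator. Monte-Carlo runs
of the full pipeline over 1000 simulated families agree with this
expectation to within ~1 standard error; the residual ~0.003 offset
traces to rare events the closed form ignores (a false call landing
within the merge gap of a true call, and cross-parent placements that
overlap by chance), both of order 10⁻³ at the default genome density.

## Problem sizes and numerical choices

Tests and the acceptance script run on scaled-down studies (3–9 families,
15–60 CNVs per parent) chosen so that each statistical check retains
power: binomial/Monte-Carlo checks use ≥1000 draws, directional checks use
100 seeded replicates, oracle-equivalence checks use 200 randomized
instances per operation on genomes small enough for per-base bitmaps.
Thresholds are validated to lie in (0,1]; threshold comparisons are
inclusive; gap comparisons are strict (<), matching the "less than 5 kb"
merging rule. Undefined ratios (empty twin call sets, empty Venn cells)
propagate as missing values, never as zeros.

## Known limitations

- Only gain/loss intervals are modelled; inversions, insertions and exact
  copy numbers are out of scope, as is parsing any caller's native output
  or VCF structural-variant records.
- Sex chromosomes are treated like autosomes when present (an
  autosome-only analysis is a matter of input filtering).
- The telomere proxy (chromosome ends) ignores acrocentric-arm and
  assembly-gap subtleties.
- The classifier assumes the three relationship classes are present and
  separable in rank order; exotic pedigrees need a different design.
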