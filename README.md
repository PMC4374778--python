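# cnvquartet

Family-aware evaluation of copy-number-variant (CNV) call sets using
monozygotic twin quartets.

CNV callers for whole-genome sequencing disagree wildly, and without a gold
standard it is hard to say which calls to trust. When a study design
includes monozygotic twins and their parents, biology itself supplies the
validation: the twins carry (to an excellent approximation) identical
genomes, and every germline CNV they carry must also be present in at least
one parent. `cnvquartet` turns that observation into a set of quantitative
quality metrics for any BED-like CNV call set, and ships a synthetic
twin-quartet simulator so the whole pipeline can be exercised — and its
statistical behaviour verified — without any sequencing data.

## What it computes

Calls are reduced to gain/loss intervals, normalized by merging same-status
calls separated by less than 5 kb (undoing caller-side fragmentation), and
compared by **reciprocal overlap (RO)**: for calls *A* and *B* the tuple
(overlap/|A|, overlap/|B|); two calls match at threshold *t* (default 0.70)
when both fractions reach *t* and the statuses agree.

On top of RO matching the toolkit provides:

- **Inherited CNV rate** per quartet: with twin call counts N₁, N₂ and
  *shared* the count of calls found in both twins and at least one parent,
  the rate is 2·shared/(N₁+N₂). Caller errors (false positives, missed
  calls, sloppy breakpoints) all push it below 1.
- **Familial-relationship classification**: pairwise sharing rates for twin,
  child–parent and random unrelated pairs are clustered with k-means
  (k = 3) and scored with the support-weighted F1 = 2PR/(P+R). Random or
  systematically biased call sets cannot separate the three relationship
  classes.
- **Cross-caller agreement**: calls from several tools are grouped into
  region components (connected components of the RO-match graph), giving
  Venn-style cell counts before and after Mendelian filtering, the per-cell
  loss ratio 1−B/A, and pairwise union/intersection call sets with their
  own inherited rates.
- **Breakpoint sensitivity**: the inherited rate is swept over an RO
  threshold grid (default 0.1–0.9); the mean slope of the curve measures
  breakpoint resolution — precise callers are barely affected by a
  stricter threshold.
- **Feature association**: calls labelled concordant/discordant by the
  Mendelian filter are annotated with size, GC content, and distances to
  telomere and centromere, then tested with a multivariate logistic
  regression under Bonferroni correction (α = 0.01/4 = 0.0025 per feature).
- **Simulator**: quartet genomes with Mendelian transmission, identical
  twins and a shared population CNV pool, observed through configurable
  virtual callers (false-positive rate, miss probability, breakpoint
  jitter, size bias, call fragmentation), with ground-truth labels on every
  emitted call.

## Worked example

Simulate a 9-family study observed through the four default virtual
callers, then score each caller:

```bash
cnvquartet simulate --seed 42 --out-dir study
cnvquartet inherited --calls-dir study --pedigree study/pedigree.tsv --out inherited.tsv
cnvquartet classify  --calls-dir study --pedigree study/pedigree.tsv --out f1.tsv
cnvquartet sweep     --calls-dir study --pedigree study/pedigree.tsv --out sweep.tsv
```

`inherited.tsv` begins (the `fragmenting` caller splits over half of its
calls and loses ~40% of them to the Mendelian filter):

```
family_id  source       n1  n2  shared  rate
F1         fragmenting  84  95  52      0.581006
F2         fragmenting  99  99  57      0.575758
F3         fragmenting  91  89  45.5    0.505556
```

All four virtual callers separate twins, child–parent and unrelated pairs
perfectly (`f1.tsv` reports `weighted_f1 = 1` for each), while the sweep
slopes in `sweep.tsv` rank the callers by breakpoint precision exactly as
their jitter settings dictate:

```
hybrid_clean  -0.104      # 100 bp jitter
rd_clean      -0.159      # 150 bp
fragmenting   -0.242      # 250 bp
pem_noisy     -0.266      # 400 bp
```

The same operations are available as library functions
(`cnvquartet.inherited_rate`, `classification_f1`, `venn_counts`,
`pairwise_setop`, `ro_sweep`, `concordance_association`, …); see
`docs/methods.md` for the underlying models and conventions.

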