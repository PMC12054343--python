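# Methods

## Model and assumptions

`hlablend` operates entirely downstream of imputation: it consumes
per-sample, per-allele evidence produced by single-panel HLA imputation
runs and combines it. Three assumptions underpin the pipeline.

1. **Binary-marker encoding.** Every two-field HLA allele is representable
   as a presence/absence marker, so a run's evidence for an allele is a
   genotype-probability triple (two presence copies, one copy, none). The
   presence posterior `p_hom + p_het/2` is half the expected allele dosage:
   ~1 for homozygous carriers, ~0.5 for heterozygous ones. Phased
   genotypes carry no extra information under this statistic and are not
   treated specially.
2. **Linear pooling.** Panels are combined by a convex combination of
   their posteriors at user weights. When an allele is covered by only a
   subset of panels, that subset's weights are rescaled to sum to 1
   (`w_X / Σ_{Y covering} w_Y`); a single-panel allele passes through
   unchanged. Merged posteriors are deliberately **not renormalised** per
   gene: the calling rule depends only on the ranking and the ratio of the
   top two posteriors, both invariant to a common positive scale, and
   renormalising would distort the pass-through semantics of
   panel-exclusive alleles.
3. **Dosage-threshold calling.** Homozygous iff the top posterior is at
   least twice the runner-up (`P1 ≥ 2·P2`, boundary inclusive). The same
   "≥" convention is used at the boundary of the pair-table adapter
   (`S1 = 2·S2` classifies homozygous).

### Pair-probability adaptation

Attribute-bagging tools report probabilities per unordered allele pair.
Per allele, `S(a)` sums all pairs containing `a`, counting a homozygous
pair once with its full probability — the plain reading of "sum the pairs
containing the allele"; double-counting homozygous pairs would make `S`
exceed 1 for certain homozygotes. Because this convention puts both
heterozygous alleles near 1 rather than 0.5, all sums are halved when
`S1 < 2·S2` (heterozygous pattern) and left unchanged otherwise, then
clipped to [0, 1].

## Key behaviours at edge cases

- **Tie-breaking in calling:** equal posteriors rank by canonical allele
  order (gene, then numeric fields), smallest first — deterministic and
  documented; no randomisation.
- **Single candidate allele:** called homozygous for it (the only
  consistent reading of the rule when no runner-up exists).
- **All-zero posteriors:** a no-call record, excluded from accuracy's
  numerator and denominator with a logged count, rather than an arbitrary
  pair.
- **Missing values inside a universe:** a sample lacking a value for an
  allele the panel's universe covers contributes posterior 0 (absence of
  evidence from that run), not panel non-membership.
- **Degenerate weights:** weight 1 on one panel reproduces it exactly on
  its universe; an allele covered only by zero-weight panels is a
  zero-mass subset and raises an error rather than silently producing 0.
- **Malformed probability triples:** triples off 1 by more than 1e-3 are
  renormalised and counted in a warning, not dropped — dropping would
  silently shrink the allele universe.
- **Weights:** must sum to 1 within 1e-9; near-miss inputs are rejected,
  not rescaled, to keep user intent explicit.
- **One-field binary markers** (two-digit suffixes) are rejected and
  skipped by the VCF reader: they have no two-field identity. Suffixes
  beyond four digits (higher-resolution names) are truncated to two fields
  with a warning, since the whole method is defined at two-field
  resolution.

## Evaluation statistics

- **Pair accuracy:** best of the two orientations of called vs truth pair,
  scored in {0, 0.5, 1}. Cohort accuracy is the per-gene mean of pair
  scores; the overall figure is the unweighted mean over genes, matching
  the convention of averaging gene-wise error rates. The stability measure
  is the unbiased sample variance over genes of the percentage error
  rates.
- **Allele frequencies** are pooled over the truth sets that contain the
  allele: frequency = chromosome count / (2 × individuals typed for the
  gene), summed over only those sets. Frequencies above 0.5 are folded to
  1−f for binning so "minor" frequency is total.
- **MAF bins** default to edges 0.01, 0.05, 0.10, 0.25 over [0, 0.5]
  (configurable). Binned accuracy fixes each pair in its best-scoring
  orientation, then scores each true allele slot against its called
  counterpart at nominal two-field resolution; empty bins report NaN, not
  0. Reusing the best orientation keeps the binned statistic consistent
  with the headline pair accuracy.
- **P-group collapsing** is supported through a user-supplied two-column
  allele → group mapping; no nomenclature database is bundled (licensing
  and versioning are out of scope), and deprecated allele names are
  handled by an exclusion list that removes affected pairs from both
  numerator and denominator.

## Weight tuning

Without an independent validation cohort, the target set is split into two
near-equal halves (seeded, unstratified — no covariate is available to
stratify on). Each half in turn serves as the validation set: candidate
panels are ranked by single-panel accuracy, and merge weights are chosen
by exhaustive search over all compositions of 1 in multiples of the step
(default 0.1) with every component ≥ one step, so no panel is zeroed
during tuning. Ties break toward the most uniform vector — equal weights
are the sensible prior when panels perform similarly. When the two fold
directions disagree, both choices and the validation-accuracy gap are
reported; they are never averaged, since the disagreement itself is the
signal that the choice is unstable. Size-based schemes (w ∝ N, √N, ln N)
are provided as alternatives; ln N is undefined for a size-1 panel (zero
mass) and is rejected rather than patched.

## Synthetic data generator

The generator emulates the ensemble's operating regime, not any real
cohort. Per gene, allele frequencies are drawn from a symmetric
Dirichlet(α = 0.5 by default, 12 alleles per gene over five classical loci
A/B/C/DQB1/DRB1) — a small α gives the skewed spectra typical of HLA, with
a few common and many rare alleles. Genotypes follow Hardy–Weinberg
proportions. Each simulated panel has:

- a **coverage fraction**: a uniform random subset of each gene's alleles,
  always including the most frequent allele (no real panel misses the
  modal allele); a truth allele outside the universe is always replaced by
  a confuser — the irreducible error coverage causes;
- an **error rate ε**: with probability ε one true allele is swapped for a
  confuser drawn frequency-weighted from the covered alleles, reflecting
  that common alleles attract misassignment;
- a **sharpness κ**: emitted posterior vectors are Dirichlet draws over
  the covered alleles with concentration κ on the (possibly corrupted)
  truth — mass 1 on a homozygote's allele, 0.5/0.5 on a heterozygote —
  plus a floor of 0.05 on every covered allele so no posterior is exactly
  zero. Vectors therefore sum to 1 per sample × gene.

Random streams are keyed per (seed, operation, panel, gene), so adding a
panel never perturbs the truth or other panels' draws.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, SNP markers and the imputation process itself,
correlated errors between panels built from overlapping cohorts, and
real reference-panel frequency spectra. Tests passing on this model show
that the merging, calling, evaluation and tuning machinery behaves as
specified and that the ensemble's qualitative advantages (error averaging,
coverage union) materialise when panel errors are independent; they do not
certify accuracy levels on real cohorts, where panel errors correlate.

## Problem sizes and numerical choices

The test suite and examples run the improvement and weight-recovery
studies at 500 samples × 5 genes × 2 panels over 20 seeds, and oracle
equivalence checks at ≤ 4 panels, ≤ 6 alleles, ≤ 5 samples over 1000
random instances — sizes at which the binomial noise on an accuracy
estimate (≈ 0.01) is far smaller than the effects being demonstrated
(5–10 accuracy points). Probability-triple tolerance is 1e-3 (engines emit
rounded values); weight-sum tolerance 1e-9; merge equivalence asserted at
1e-12. TSV round-trips are exact to 1e-9 via 10-significant-digit
formatting.

## Known limitations

- Calling supports exactly two-field resolution; higher fields are
  truncated on input.
- The merge assumes one global weight per panel (no per-gene weights) and
  intersects sample sets by default; the union mode rescales weights per
  sample over the panels containing it.
- Phased input receives no special treatment, and no posterior-threshold
  quality filter is applied to calls.
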