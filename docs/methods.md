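# Methods

This note records the statistical model, the defaults and the design
choices behind `monosig`, in the order the pipeline runs.

## Expression model and scales

Expression values are linear-scale intensities throughout the public API
(matrices on disk, scores, the mean-difference filter). All location-based
statistics — quantile reference averaging aside — are computed on the log2
scale: effect sizes, co-normalization offsets, simulation noise. This
matches microarray practice, where intensities are roughly log-normal and
standardized effects are only meaningful on the log scale, while filters
phrased in "expression units" (the 32-unit mean-difference floor) read
naturally on the linear scale. Whether that floor should instead apply to
log2 values is genuinely open; linear is the default and the
`SelectionCriteria.min_mean_diff` field is configurable.

## Normalization

**Quantile normalization** forces every sample of a study onto the common
empirical distribution: the reference is the per-rank mean of the samples'
sorted non-missing values. With missing values the samples' sorted vectors
have unequal lengths, so each is linearly interpolated onto a common
quantile grid (length = the largest non-missing count) before averaging,
and each sample reads the reference back at its own grid. Ties within a
sample receive the reference value at their average rank. On complete data
the transform is exactly the classical per-rank-mean algorithm and is
idempotent; with missing data the interpolation makes idempotence
approximate, which is why the package's exactness guarantees are stated
for complete matrices.

**Probe summarization** is the unweighted arithmetic mean of a gene's
probes per sample; probes mapping to several genes contribute to each.
Variance-weighted alternatives exist but are order-dependent in the
presence of missing values and buy little on modern annotations.

**Co-normalization** shifts, per gene and study, the study's log2 values so
that its mean over sorted-subset samples equals the unweighted mean of the
per-study means across studies measuring the gene. This is the minimal
location adjustment that equalizes study locations; because Hedges' g is
invariant to adding a constant to both groups, it provably changes no
within-study standardized effect. It deliberately does not touch scale
(no per-study variance rescaling): scale adjustments would alter g and
would need a justification the integration model does not supply. The
transform sits behind a single function so a different strategy can be
swapped in. Genes measured in no study are dropped with a warning; genes
missing in one study stay missing there and are simply absent from that
study's effect estimates — never imputed.

## Meta-analysis

Per gene and study, Hedges' g compares the subset of interest against all
other sorted samples (mixed-cell samples are excluded from both groups;
with three subsets present, the two non-target subsets together form the
control group). Studies contribute only when both groups have ≥ 2 samples
and the pooled spread is positive. Pooling is DerSimonian–Laird with τ²
truncated at 0 and a normal-approximation two-sided p — the conventional
large-sample meta-analysis treatment; REML/HKSJ refinements are out of
scope. With one study the pooled effect reduces to that study's g. The
per-gene linear-scale mean difference is pooled with fixed-effect weights
(1/var(g)) for the selection filter. `min_studies` (default 1) controls
the coverage floor; discovery-scale analyses typically require ≥ 4.
Benjamini–Hochberg adjustment runs across all genes that produced a pooled
effect. Ranking ties are broken by smaller FDR, then gene symbol, making
every downstream selection deterministic and order-independent.

The per-compendium driver (`run_meta`) computes all genes of a study in
one vectorized pass; unit tests pin it to the scalar `hedges_g` /
`pool_random_effects` route, and an independent reference implementation
(R's `metafor`, DL method) is used as the oracle for pooling in the test
suite.

## Signature selection

Four rules, applied to the pooled table: rank by pooled g descending; keep
pooled g > 0; keep FDR ≤ `fdr_max` (default 0.05 — the published procedure
prints no explicit cutoff, so the conventional level is the recorded
default); keep pooled linear mean difference ≥ `min_mean_diff` (default
32); return the first `top_k` (default 10) survivors. Fewer survivors than
`top_k` yields the survivors plus a shortfall flag; zero survivors is an
error that reports how many genes each filter removed. Loosening any
single criterion can only grow the selected set (tested property).

The bundled published signatures carry the intermediate-monocyte list
verbatim (with the printed symbols ATP50 / DX39A preserved and their
likely-intended symbols ATP5O / DDX39A as aliases). The classical and
nonclassical entries are partial: they contain only the genes the primary
publication text itself names (SIGLEC10, IER2, CTSA for nonclassical;
the classical-elevated surface markers CSF3R, FCGR2A, CD36, IL17RA), the
full top-10 lists living in supplementary material not redistributed here;
their docstring says so.

## Scoring and evaluation

A signature score is the geometric mean of the signature genes' linear
expression in a sample, with values floored at 1 linear unit so zeros
cannot annihilate the product (the floor is configurable; on log-scale
data the geometric mean of anti-logged values equals the anti-log of the
mean, so sample orderings are unaffected by the scale convention). Genes
absent from a dataset reduce the gene count k rather than invalidate the
score — cross-platform application is the central use case — guarded by a
minimum coverage of 50% of the signature. Gene symbols match
case-insensitively.

AUROC is the Mann–Whitney statistic with midrank ties; its 95% CI uses
DeLong's placement variances (a bootstrap CI was considered and rejected
as needlessly stochastic for a deterministic pipeline). Group comparisons
default to Welch's unequal-variance t-test, with Wilcoxon rank-sum
(signed-rank when paired) as the nonparametric option. Score–fraction
validation uses Pearson correlation with the t-distribution p-value. The
intermediate-ordering check declares a transitional pattern when the
middle subset's mean score lies strictly between the two pure subsets'
means.

## Enrichment

Pre-ranked GSEA on a pooled effect-size vector: weighted KS running sum
with hit increments ∝ |effect|^1 (the classic weighted default; exponent
configurable, 0 gives the unweighted statistic) and uniform miss
decrements; ES is the deviation of maximum magnitude, computed exactly by
visiting only hit positions. The null is gene-label permutation (random
same-size sets), p-values and the NES normalization are sign-matched
(computed among permutation scores of the observed sign), and permutation
scores are cached per set size. A set spanning the entire ranking has
ES = 0 by convention. Sets with fewer than 3 ranked members or more than
half the ranking are skipped and reported. Defaults: 10⁴ permutations,
explicit seed.

## Synthetic data

The generator emulates a heterogeneous sorted-cell compendium, not any
particular repository: per-gene baselines are drawn once (linear mean
256 ± 64, clipped positive, shared across studies), samples are log2-normal
with within-group sd 0.5 log2 units, each study receives one additive
log2-scale batch shift (sd 0.5 — study-to-study heterogeneity is not
quantified anywhere authoritative, so this is a plausible free choice) and
drops a random 10% of genes (platform coverage). Markers are disjoint
gene sets per subset whose log2 means are raised by
`planted_effect_size × within_sd`, so the realized Hedges' g targets the
planted value; defaults (6 studies, 10 samples per subset per study,
1000 genes, 10 markers per subset, g = 2) are the package's reference
study conditions, and with baseline means near 256 the planted one-log2
shift implies linear mean differences of hundreds of units, comfortably
above the 32-unit filter. The intermediate subset, when enabled, is a
λ-mixture of the two pure log2 profiles with no markers of its own —
the transitional-state model. Mixed-cell samples are convex combinations
of subset mean profiles on the linear scale with Dirichlet fractions and
optional log-normal noise. A single seed feeds a hierarchical per-study
stream (`numpy.random.SeedSequence.spawn`), so outputs are bit-reproducible
and studies are independent.

What the generator does not emulate: probe-level structure, count-based
RNA-seq noise (log-normal stands in for log-transformed counts),
gene–gene correlation, subset-specific variance differences, and
non-location batch effects (scale or rank distortions). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artifact of real public data.

## Problem sizes and numerics

Test and acceptance runs use the reference conditions above (the null
calibration uses replicated 6-study × 1000-gene compendia; enrichment
nulls use 10³ permutations), sizes at which every stage runs in seconds.
Degenerate inputs fail loudly: zero pooled spread is an undefined effect,
single-sample studies cannot be quantile normalized, one-class label
vectors cannot produce an AUROC, zero-variance vectors cannot be
correlated. Tolerances in the package's own guarantees are 1e-9 for exact
location-shift identities and 1e-8 against the independent pooling
reference. Output files round floats to 10 significant digits, which is
what makes rerun manifests byte-identical.

## Known limitations

Co-normalization here is one defensible strategy, not a reconstruction of
any specific prior tool's transform. The DeLong CI is asymptotic and
degenerates at AUROC 1 with small n (the CI collapses to the point). BH
controls FDR under independence/PRDS; effect estimates across genes from
shared control groups are correlated, so the null-calibration guarantee is
empirical, not a theorem. The 4-rule selection inherits the published
procedure's simplicity — it does not consider redundancy among top genes.
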