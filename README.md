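# monosig

Multi-cohort discovery and scoring of monocyte-subset gene expression
signatures.

## The problem

Human blood monocytes fall into classical (CD14+CD16−), nonclassical
(CD14−CD16+) and intermediate (CD14+CD16+) subsets whose proportions shift
in disease and under treatment. Public repositories hold hundreds of
expression profiles of sorted monocytes, but they span dozens of studies
and platforms, each with its own location and coverage biases. `monosig`
implements a meta-analytic pipeline that integrates such heterogeneous
cohorts into robust, parsimonious subset signatures and then uses those
signatures to score any expression sample — sorted cells, PBMCs or whole
blood — for its monocyte-subset content.

The package is aimed at computational immunologists who want to (a) derive
cell-subset signatures from multiple sorted-cell cohorts and (b) apply
geometric-mean signature scores to bulk data as a lightweight alternative
to full cell-mixture deconvolution.

## The method

For each gene and study, the standardized mean difference between the
subset of interest and all other sorted samples is computed on the log2
scale as Hedges' g:

    d = (m₁ − m₀) / s_pooled,   J = 1 − 3/(4(n₁+n₀) − 9),   g = J·d
    var(g) = (n₁+n₀)/(n₁n₀) + g²/(2(n₁+n₀))

Study effects are pooled per gene with DerSimonian–Laird random effects:
fixed-effect weights wᵢ = 1/var(gᵢ) give Cochran's Q and
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)); random-effects weights
1/(var(gᵢ)+τ²) yield the pooled effect, its SE, a normal z and a two-sided
p, corrected across genes by Benjamini–Hochberg. Before the meta-analysis,
each study is quantile normalized, probe-level features are collapsed to
gene symbols by averaging, and studies are co-normalized (per-gene
log2-scale mean-centering to the cross-study mean, which provably leaves
every within-study g unchanged).

Signatures are selected by four rules: rank genes by pooled g, keep genes
over-expressed in the subset (pooled g > 0 at FDR ≤ 0.05), keep genes with
a pooled linear-scale mean expression difference ≥ 32 units, take the top
10. A sample's signature score (cMSS / ncMSS for the classical /
nonclassical signatures) is the geometric mean of the signature genes'
linear expression. Scores are evaluated by AUROC with a DeLong 95% CI,
Welch t / Wilcoxon tests between groups, and Pearson correlation against
measured cell fractions. A pre-ranked, permutation-based gene-set
enrichment module tests gene sets against pooled effect-size rankings.

A synthetic-data module generates multi-study sorted-subset compendia with
planted markers of known effect size, study batch shifts, platform-style
gene dropout, transitional (intermediate) profiles and mixed-cell samples
with known fractions, so the whole pipeline is testable end to end without
any downloads.

## Worked example

```python
import monosig as ms

cfg = ms.SimulationConfig(seed=42)            # 6 studies, 10+10 samples each,
datasets, truth = ms.simulate_sorted_studies(cfg)  # 1000 genes, planted g = 2

normalized = [ms.quantile_normalize(d) for d in datasets]
aligned, _ = ms.align_genes(normalized, mode="union")
conorm = ms.conormalize(aligned)

meta = ms.run_meta(conorm, "classical")
outcome = ms.select_signature(meta, ms.SelectionCriteria(), "classical")
planted = set(truth.marker_genes_by_subset["classical"])
print(len(planted & set(outcome.signature.genes)), "of 10 planted markers recovered")
```

prints

```
10 of 10 planted markers recovered
```

i.e. the pooled effect-size ranking puts all planted classical markers at
the top despite per-study batch shifts and 10% gene dropout. Scoring the
sorted compendium with the selected signature
(`ms.score_table(conorm, [outcome.signature])`) separates classical from
all other sorted samples with `AUROC = 1.000` — the classical score of
every classical sample exceeds that of every other sample. The
`examples/` directory contains short narrative scripts for each
capability (discovery, scoring/evaluation, mixtures and the transitional
subset, enrichment); `monosig --help` exposes the same stages as a CLI,
and `monosig run --config pipeline.yaml` executes the whole pipeline with
a reproducible manifest.

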