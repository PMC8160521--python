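"""Discover subset markers from a synthetic multi-study compendium.

Generates six sorted-monocyte studies with ten planted classical and ten
planted nonclassical markers (Hedges' g = 2), normalizes them, runs the
per-gene random-effects meta-analysis and applies the 4-rule selection.
"""

import monosig as ms

cfg = ms.SimulationConfig(seed=42)
datasets, truth = ms.simulate_sorted_studies(cfg)
print(f"simulated {len(datasets)} studies, "
      f"{datasets[0].values.shape[0]} genes x {datasets[0].values.shape[1]} samples each")

normalized = [ms.quantile_normalize(d) for d in datasets]
aligned, coverage = ms.align_genes(normalized, mode="union")
conorm = ms.conormalize(aligned)

meta = ms.run_meta(conorm, "classical")
print("\ntop 5 genes by pooled Hedges' g (classical vs rest):")
print(meta.head(5)[["pooled_g", "se", "fdr", "pooled_mean_diff_linear"]].round(3))

outcome = ms.select_signature(meta, ms.SelectionCriteria(), "classical")
planted = set(truth.marker_genes_by_subset["classical"])
hits = len(planted & set(outcome.signature.genes))
print(f"\nselected signature: {outcome.signature.genes}")
print(f"{hits}/10 selected genes are planted classical markers — the "
      "meta-analysis recovers the ground truth despite batch shifts and dropout.")
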