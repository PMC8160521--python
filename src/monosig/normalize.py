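"""Per-study quantile normalization, probe-to-gene summarization, and
cross-study co-normalization.

The pipeline order follows standard multi-cohort practice: quantile
normalize each study, collapse probes to gene symbols, then co-normalize
the gene-level studies onto a common per-gene location. Co-normalization is
realized as per-gene, per-study mean-centering to the global cross-study
mean on the log2 scale — the minimal location adjustment that equalizes
study locations while provably preserving every within-study standardized
effect size (Hedges' g is invariant to adding a constant to both groups).
It is exposed behind one interface so a different strategy can replace it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .errors import InsufficientDataError, SchemaError

_LOG_FLOOR = 1e-12  # guards log2 of non-positive intensities


@dataclass
class NormalizationReport:
    """Bookkeeping for one normalization run: what was done to each study."""

    quantile_reference: dict[str, int] = field(default_factory=dict)  # study -> ref length
    probes_collapsed: dict[str, int] = field(default_factory=dict)
    probes_unmapped: dict[str, int] = field(default_factory=dict)
    genes_out: dict[str, int] = field(default_factory=dict)
    conorm_offsets: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "quantile_reference": self.quantile_reference,
            "probes_collapsed": self.probes_collapsed,
            "probes_unmapped": self.probes_unmapped,
            "genes_out": self.genes_out,
            "conorm_offsets": self.conorm_offsets,
        }


def quantile_normalize(
    dataset: ExpressionDataset, report: NormalizationReport | None = None
) -> ExpressionDataset:
    """Force every sample onto the common empirical distribution.

    The reference distribution is the per-rank mean of the samples' sorted
    non-missing values; when missing values make the samples' lengths
    unequal, each sample's sorted values are linearly interpolated onto a
    common quantile grid before averaging, and the reference is read back at
    the sample's own grid. Within-sample ranks are preserved; ties receive
    the reference value at their average rank.
    """
    X = dataset.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise InsufficientDataError(
            f"quantile normalization needs >= 2 samples, study {dataset.study_id!r} has {n_samp}"
        )
    counts = (~np.isnan(X)).sum(axis=0)
    if (counts < 1).any():
        bad = [dataset.values.columns[j] for j in np.where(counts < 1)[0]]
        raise InsufficientDataError(f"samples with no measured values: {bad}")

    n_ref = int(counts.max())
    common_grid = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.5])
    ref_sum = np.zeros(n_ref)
    for j in range(n_samp):
        vals = np.sort(X[~np.isnan(X[:, j]), j])
        nj = len(vals)
        grid_j = np.linspace(0.0, 1.0, nj) if nj > 1 else np.array([0.5])
        ref_sum += np.interp(common_grid, grid_j, vals)
    reference = ref_sum / n_samp

    out = np.full_like(X, np.nan)
    for j in range(n_samp):
        mask = ~np.isnan(X[:, j])
        col = X[mask, j]
        nj = len(col)
        # average ranks map ties to the mean of their reference values
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(nj)
        ranks[order] = np.arange(1, nj + 1)
        # midrank adjustment for ties
        sorted_col = col[order]
        i = 0
        while i < nj:
            k = i
            while k + 1 < nj and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranks[order[i:k + 1]] = (i + 1 + k + 1) / 2.0
            i = k + 1
        q = (ranks - 1.0) / (nj - 1.0) if nj > 1 else np.full(nj, 0.5)
        out[mask, j] = np.interp(q, common_grid, reference)

    if report is not None:
        report.quantile_reference[dataset.study_id] = n_ref
    values = pd.DataFrame(out, index=dataset.values.index, columns=dataset.values.columns)
    return dataset.with_values(values)


def summarize_probes(
    dataset: ExpressionDataset,
    probe_map: pd.DataFrame,
    report: NormalizationReport | None = None,
) -> ExpressionDataset:
    """Collapse probe-level features to gene symbols.

    Per gene and sample, expression is the arithmetic mean of the gene's
    probes' values (missing probes excluded pairwise). A probe mapping to
    several genes contributes to each of them; probes absent from the map
    are dropped and counted in the report.
    """
    if not {"probe_id", "gene_symbol"} <= set(probe_map.columns):
        raise SchemaError("probe map must have probe_id and gene_symbol columns")
    pm = probe_map[probe_map["probe_id"].isin(dataset.values.index)]
    if pm.empty:
        raise SchemaError(
            f"no probe of study {dataset.study_id!r} maps to any gene"
        )
    expanded = dataset.values.loc[pm["probe_id"]]
    expanded.index = pd.Index(pm["gene_symbol"].to_numpy(), name="gene")
    gene_values = expanded.groupby(level=0, sort=True).mean()

    if report is not None:
        probes = set(dataset.values.index)
        mapped = set(pm["probe_id"])
        report.probes_collapsed[dataset.study_id] = len(mapped)
        report.probes_unmapped[dataset.study_id] = len(probes - mapped)
        report.genes_out[dataset.study_id] = gene_values.shape[0]
    return dataset.with_values(gene_values)


def conormalize(
    datasets: list[ExpressionDataset],
    report: NormalizationReport | None = None,
) -> list[ExpressionDataset]:
    """Equalize per-gene study locations across gene-aligned studies.

    For every gene, each study's log2 values are shifted so the study's mean
    over its sorted-subset samples equals the unweighted global mean of the
    per-study means (computed over studies that measure the gene). Values
    are returned on the linear scale. Within-study between-class differences
    are preserved exactly; genes measured by no study are dropped with a
    warning; genes a study does not measure stay missing in that study.
    """
    if len(datasets) < 2:
        raise InsufficientDataError("co-normalization needs >= 2 datasets")
    index = datasets[0].values.index
    for ds in datasets[1:]:
        if not ds.values.index.equals(index):
            raise SchemaError(
                "datasets must be gene-aligned (union mode) before co-normalization"
            )

    study_means = np.full((len(index), len(datasets)), np.nan)
    log2_all = []
    for k, ds in enumerate(datasets):
        log2_vals = np.log2(
            np.clip(ds.values.to_numpy(dtype=float), _LOG_FLOOR, None)
        )
        log2_vals[np.isnan(ds.values.to_numpy(dtype=float))] = np.nan
        log2_all.append(log2_vals)
        ref_cols = [ds.values.columns.get_loc(s) for s in ds.sorted_sample_ids()]
        if not ref_cols:
            ref_cols = list(range(ds.values.shape[1]))  # all-mixed study: use all samples
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            study_means[:, k] = np.nanmean(log2_vals[:, ref_cols], axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_mean = np.nanmean(study_means, axis=1)
    unmeasured = np.isnan(global_mean)
    if unmeasured.any():
        warnings.warn(
            f"{int(unmeasured.sum())} gene(s) measured in no study were dropped",
            stacklevel=2,
        )

    out = []
    for k, ds in enumerate(datasets):
        offsets = global_mean - study_means[:, k]
        shifted = log2_all[k] + offsets[:, None]
        values = pd.DataFrame(
            np.power(2.0, shifted), index=index, columns=ds.values.columns
        )
        if unmeasured.any():
            values = values.loc[~unmeasured]
        out.append(ds.with_values(values))
        if report is not None:
            finite = np.isfinite(offsets)
            report.conorm_offsets[ds.study_id] = {
                "mean_abs_offset": float(np.mean(np.abs(offsets[finite]))) if finite.any() else 0.0,
                "n_genes_shifted": int(finite.sum()),
            }
    return out
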