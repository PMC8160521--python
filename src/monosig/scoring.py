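"""Geometric-mean signature scores and their evaluation.

A sample's score for a signature (e.g. the classical and nonclassical
monocyte subset scores, cMSS and ncMSS) is the geometric mean of the
linear-scale expression of the signature genes present in the dataset.
Missing genes reduce the gene count rather than invalidate the score, with
a minimum-coverage guard; values are floored at 1 linear unit before the
log so zeros cannot annihilate the product.

Evaluation helpers: AUROC (Mann–Whitney with midrank ties) with a DeLong
95% CI, two-group comparisons (Welch t / Wilcoxon rank-sum / signed-rank),
Pearson correlation of scores against measured cell fractions, and the
three-subset ordering check for transitional intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset, Signature
from .errors import CoverageError, InsufficientDataError, ParameterError


@dataclass
class RocResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def _gene_matches(dataset_index: pd.Index, genes: list[str]) -> list[str]:
    """Signature genes found in the dataset, matched case-insensitively,
    returned as the dataset's own feature ids."""
    lookup: dict[str, str] = {}
    for feat in dataset_index:
        lookup.setdefault(str(feat).upper(), feat)
    return [lookup[g.upper()] for g in genes if g.upper() in lookup]


def score_samples(
    dataset: ExpressionDataset,
    signature: Signature,
    floor: float = 1.0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-sample geometric-mean score of one signature.

    Returns a frame indexed by sample id with the score column named after
    the signature, plus ``subset``, ``disease`` and ``study_id`` labels and
    the realized gene coverage. Genes absent from the dataset are dropped
    from the geometric mean; if fewer than ``min_coverage`` of the signature
    genes (and at least one) are present, scoring fails.
    """
    present = _gene_matches(dataset.values.index, signature.genes)
    coverage = len(present) / len(signature.genes)
    if not present:
        raise CoverageError(
            f"no gene of signature {signature.name!r} is measured in study "
            f"{dataset.study_id!r}"
        )
    if coverage < min_coverage:
        raise CoverageError(
            f"only {len(present)}/{len(signature.genes)} genes of signature "
            f"{signature.name!r} measured in study {dataset.study_id!r} "
            f"(coverage {coverage:.2f} < {min_coverage})"
        )
    vals = dataset.values.loc[present].to_numpy(dtype=float)
    floored = np.clip(vals, floor, None)
    floored[np.isnan(vals)] = np.nan
    k_present = (~np.isnan(floored)).sum(axis=0)
    if (k_present == 0).any():
        bad = [dataset.values.columns[j] for j in np.where(k_present == 0)[0]]
        raise CoverageError(f"samples with no measured signature gene: {bad}")
    with np.errstate(invalid="ignore"):
        scores = np.exp(np.nanmean(np.log(floored), axis=0))

    ann = dataset.annotations.loc[list(dataset.values.columns)]
    out = pd.DataFrame(
        {
            signature.name: scores,
            "subset": ann["subset"].to_numpy(),
            "disease": ann.get("disease", pd.Series("", index=ann.index)).to_numpy(),
            "study_id": dataset.study_id,
        },
        index=pd.Index(dataset.values.columns, name="sample_id"),
    )
    out.attrs["coverage"] = {signature.name: coverage}
    out.attrs["all_at_floor"] = bool(np.all(vals[~np.isnan(vals)] <= floor))
    return out


def score_table(
    datasets: list[ExpressionDataset] | ExpressionDataset,
    signatures: list[Signature],
    floor: float = 1.0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Score several signatures over one or more datasets; one row per
    sample, one score column per signature."""
    if isinstance(datasets, ExpressionDataset):
        datasets = [datasets]
    if not signatures:
        raise ParameterError("no signatures given")
    rows = []
    for ds in datasets:
        parts = [score_samples(ds, sig, floor, min_coverage) for sig in signatures]
        merged = parts[0]
        for part in parts[1:]:
            merged[part.columns[0]] = part[part.columns[0]]
        rows.append(merged)
    table = pd.concat(rows, axis=0)
    label_cols = ["subset", "disease", "study_id"]
    return table[[s.name for s in signatures] + label_cols]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> RocResult:
    """AUROC of ``scores`` against binary ``labels`` (1 = positive class).

    Computed as the Mann–Whitney U statistic divided by n_pos * n_neg with
    ties counted 0.5; the 95% CI uses DeLong's covariance structure
    (clipped to [0, 1]; degenerate with a single positive or negative).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ParameterError("scores and labels must be 1-D and equal length")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ParameterError(f"labels must contain exactly 2 classes, got {classes!r}")
    pos = s[y == classes.max()]
    neg = s[y == classes.min()]
    m, n = len(pos), len(neg)

    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong placements
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zcrit = stats.norm.ppf(0.975)
    lo = min(max(auc - zcrit * se, 0.0), auc)
    hi = max(min(auc + zcrit * se, 1.0), auc)
    return RocResult(auroc=float(auc), ci_low=float(lo), ci_high=float(hi),
                     n_pos=m, n_neg=n)


def compare_groups(
    scores, groups, test: str = "t", paired: bool = False
) -> tuple[float, float]:
    """Two-sided comparison of scores between two groups.

    ``test='t'`` uses Welch's unequal-variance t-test (paired t when
    ``paired``); ``test='wilcoxon'`` uses the rank-sum test (signed-rank
    when ``paired``). Returns (statistic, p).
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ParameterError(f"groups must contain exactly 2 labels, got {labels!r}")
    a, b = s[g == labels[0]], s[g == labels[1]]
    if paired and len(a) != len(b):
        raise ParameterError("paired comparison needs equal group sizes")
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if test == "t":
        res = stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        if paired:
            res = stats.wilcoxon(a, b, zero_method="zsplit", method="approx")
        else:
            res = stats.ranksums(a, b)
    else:
        raise ParameterError(f"unknown test {test!r}; use 't' or 'wilcoxon'")
    return float(res.statistic), float(res.pvalue)


def correlate_with_fractions(scores, fractions) -> tuple[float, float]:
    """Pearson correlation of signature scores against measured cell
    fractions, with the two-sided t-distribution p-value."""
    s = np.asarray(scores, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if s.shape != f.shape or s.ndim != 1:
        raise ParameterError("scores and fractions must be 1-D and equal length")
    if len(s) < 3:
        raise InsufficientDataError("correlation needs >= 3 samples")
    if np.std(s) == 0 or np.std(f) == 0:
        raise ParameterError("zero variance in scores or fractions; correlation undefined")
    r, p = stats.pearsonr(s, f)
    return float(r), float(p)


def ordering_check(
    table: pd.DataFrame,
    score_column: str,
    subsets: tuple[str, str, str] = ("classical", "intermediate", "nonclassical"),
) -> tuple[bool, dict[str, float]]:
    """True iff the middle subset's mean score lies strictly between the two
    flanking subsets' means (a transitional intermediate); also returns the
    three group means."""
    lo_lab, mid_lab, hi_lab = subsets
    means = {}
    for lab in subsets:
        sel = table["subset"] == lab
        if not sel.any():
            raise ParameterError(f"subset {lab!r} has no samples in the score table")
        means[lab] = float(table.loc[sel, score_column].mean())
    lo, mid, hi = means[lo_lab], means[mid_lab], means[hi_lab]
    between = min(lo, hi) < mid < max(lo, hi)
    return bool(between), means
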