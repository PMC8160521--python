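"""Per-gene Hedges' g within studies and DerSimonian–Laird random-effects
pooling across studies, with Benjamini–Hochberg multiplicity correction.

For each gene and study, the standardized mean difference between the cell
subset of interest and all other sorted samples is computed on the log2
scale:

    d = (m1 - m0) / s_pooled,      s_pooled^2 = ((n1-1)s1^2 + (n0-1)s0^2) / (n1+n0-2)
    J = 1 - 3 / (4(n1+n0) - 9),    g = J * d
    var_g = (n1+n0)/(n1*n0) + g^2 / (2(n1+n0))

Study effects are pooled per gene by the DerSimonian–Laird moment
estimator: fixed-effect weights w_i = 1/var_i give Cochran's
Q = sum w_i (g_i - g_FE)^2, tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2/sum w)),
random-effects weights 1/(var_i + tau^2), and a normal-approximation
two-sided p on z = pooled_g / se. The linear-scale case-minus-control mean
difference is tracked separately (inverse-variance weighted across studies)
for the downstream expression-difference filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset, MIXED_LABEL
from .errors import InsufficientDataError, ParameterError, UndefinedEffectError


@dataclass
class StudyEffect:
    """One gene's standardized effect in one study."""

    gene: str
    study_id: str
    g: float
    var_g: float
    n_case: int
    n_control: int
    mean_diff_linear: float = np.nan


@dataclass
class MetaResult:
    """One gene's pooled random-effects summary across studies."""

    gene: str
    pooled_g: float
    se: float
    tau2: float
    q_stat: float
    n_studies: int
    z: float
    p: float
    fdr: float = np.nan
    pooled_mean_diff_linear: float = np.nan


def hedges_g(case_values, control_values) -> tuple[float, float]:
    """Hedges' g (bias-corrected standardized mean difference) and its
    sampling variance between two groups of values.

    Values are used as given; callers working with linear intensities
    should pass log2-transformed values. Missing values must be removed by
    the caller.
    """
    x1 = np.asarray(case_values, dtype=float)
    x0 = np.asarray(control_values, dtype=float)
    n1, n0 = len(x1), len(x0)
    if n1 < 2 or n0 < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 values (got {n1} case, {n0} control)"
        )
    if np.isnan(x1).any() or np.isnan(x0).any():
        raise ParameterError("hedges_g received NaN values; drop missing values first")
    v1, v0 = x1.var(ddof=1), x0.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    if sp2 <= 0:
        raise UndefinedEffectError("pooled standard deviation is zero; g undefined")
    d = (x1.mean() - x0.mean()) / np.sqrt(sp2)
    n = n1 + n0
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    g = j * d
    var_g = n / (n1 * n0) + g * g / (2.0 * n)
    return float(g), float(var_g)


def pool_random_effects(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of one gene's study effects.

    With a single study the pooled effect reduces to that study's g with
    tau^2 = 0.
    """
    if not effects:
        raise ParameterError("pool_random_effects requires at least one study effect")
    gene = effects[0].gene
    g = np.array([e.g for e in effects], dtype=float)
    var = np.array([e.var_g for e in effects], dtype=float)
    if np.any(var <= 0):
        raise ParameterError("all effect variances must be > 0")
    md = np.array([e.mean_diff_linear for e in effects], dtype=float)

    pooled, se, tau2, q = _dl_pool(g, var)
    z = pooled / se
    p = 2.0 * stats.norm.sf(abs(z))
    w = 1.0 / var
    pooled_md = float(np.nansum(w * md) / w[~np.isnan(md)].sum()) if (~np.isnan(md)).any() else np.nan
    return MetaResult(
        gene=gene, pooled_g=float(pooled), se=float(se), tau2=float(tau2),
        q_stat=float(q), n_studies=len(effects), z=float(z), p=float(p),
        pooled_mean_diff_linear=pooled_md,
    )


def _dl_pool(g: np.ndarray, var: np.ndarray) -> tuple[float, float, float, float]:
    """Scalar DL pooling on one gene; returns (pooled, se, tau2, Q)."""
    w = 1.0 / var
    sw = w.sum()
    g_fe = (w * g).sum() / sw
    q = float((w * (g - g_fe) ** 2).sum())
    k = len(g)
    if k > 1:
        c = sw - (w ** 2).sum() / sw
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    w_re = 1.0 / (var + tau2)
    pooled = (w_re * g).sum() / w_re.sum()
    se = np.sqrt(1.0 / w_re.sum())
    return float(pooled), float(se), float(tau2), q


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("pvals must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorized per-compendium driver
# ---------------------------------------------------------------------------

def _study_effects_matrix(
    dataset: ExpressionDataset, subset_of_interest: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Per-gene (g, var_g, mean_diff_linear) arrays for one study, NaN where
    the effect is undefined (coverage or degenerate spread)."""
    labels = dataset.subset_labels()
    sorted_mask = (labels != MIXED_LABEL).to_numpy()
    case_mask = (labels == subset_of_interest).to_numpy() & sorted_mask
    ctrl_mask = (labels != subset_of_interest).to_numpy() & sorted_mask
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        return None

    linear = dataset.values.to_numpy(dtype=float)
    log2_vals = np.log2(np.clip(linear, 1e-12, None))
    log2_vals[np.isnan(linear)] = np.nan

    def _stats(mask):
        x = log2_vals[:, mask]
        n = (~np.isnan(x)).sum(axis=1).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(x, axis=1)
            v = np.nanvar(x, axis=1, ddof=1)
        return n, m, v

    n1, m1, v1 = _stats(case_mask)
    n0, m0, v0 = _stats(ctrl_mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        valid = (n1 >= 2) & (n0 >= 2) & (sp2 > 0)
        d = (m1 - m0) / np.sqrt(sp2)
        n = n1 + n0
        j = 1.0 - 3.0 / (4.0 * n - 9.0)
        g = j * d
        var_g = n / (n1 * n0) + g * g / (2.0 * n)
    g[~valid] = np.nan
    var_g[~valid] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        md = np.nanmean(linear[:, case_mask], axis=1) - np.nanmean(linear[:, ctrl_mask], axis=1)
    md[~valid] = np.nan
    return g, var_g, md


def run_meta(
    datasets: list[ExpressionDataset],
    subset_of_interest: str,
    min_studies: int = 1,
) -> pd.DataFrame:
    """Per-gene meta-analysis of ``subset_of_interest`` versus all other
    sorted samples across gene-aligned studies.

    Studies contributing fewer than 2 case or 2 control samples are skipped;
    genes measured (with a defined effect) in fewer than ``min_studies``
    studies are excluded. Returns a frame indexed by gene with columns
    ``pooled_g, se, tau2, q_stat, n_studies, z, p, fdr,
    pooled_mean_diff_linear``, sorted by pooled_g descending (ties: smaller
    fdr, then gene symbol).
    """
    if min_studies < 1:
        raise ParameterError("min_studies must be >= 1")
    if not datasets:
        raise ParameterError("run_meta requires at least one dataset")
    index = datasets[0].values.index
    for ds in datasets[1:]:
        if not ds.values.index.equals(index):
            raise ParameterError("datasets must be gene-aligned before run_meta")

    per_study = [_study_effects_matrix(ds, subset_of_interest) for ds in datasets]
    per_study = [t for t in per_study if t is not None]
    if not per_study:
        raise InsufficientDataError(
            f"no study has >= 2 samples of {subset_of_interest!r} and >= 2 others"
        )

    G = np.vstack([t[0] for t in per_study])  # studies x genes
    V = np.vstack([t[1] for t in per_study])
    MD = np.vstack([t[2] for t in per_study])
    defined = ~np.isnan(G)
    k = defined.sum(axis=0)
    eligible = k >= min_studies

    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(defined, 1.0 / V, 0.0)
        sw = W.sum(axis=0)
        g_fe = np.where(sw > 0, np.nansum(W * np.where(defined, G, 0.0), axis=0) / sw, np.nan)
        q = np.nansum(W * np.where(defined, (G - g_fe) ** 2, 0.0), axis=0)
        c = sw - (W ** 2).sum(axis=0) / np.where(sw > 0, sw, np.nan)
        tau2 = np.where(
            (k > 1) & (c > 0), np.maximum(0.0, (q - (k - 1)) / c), 0.0
        )
        W_re = np.where(defined, 1.0 / (V + tau2[None, :]), 0.0)
        sw_re = W_re.sum(axis=0)
        pooled = np.nansum(W_re * np.where(defined, G, 0.0), axis=0) / sw_re
        se = np.sqrt(1.0 / sw_re)
        z = pooled / se
        md_defined = defined & ~np.isnan(MD)
        w_md = np.where(md_defined, W, 0.0)
        pooled_md = np.where(
            w_md.sum(axis=0) > 0,
            np.nansum(w_md * np.where(md_defined, MD, 0.0), axis=0) / w_md.sum(axis=0),
            np.nan,
        )
    p = 2.0 * stats.norm.sf(np.abs(z))

    result = pd.DataFrame(
        {
            "pooled_g": pooled,
            "se": se,
            "tau2": tau2,
            "q_stat": q,
            "n_studies": k,
            "z": z,
            "p": p,
            "pooled_mean_diff_linear": pooled_md,
        },
        index=index,
    )
    result = result.loc[eligible & (k > 0)]
    if result.empty:
        raise InsufficientDataError(
            f"no gene measured in >= {min_studies} studies with a defined effect"
        )
    result["fdr"] = benjamini_hochberg(result["p"].to_numpy())
    result.index.name = "gene"
    result = result.reset_index()
    result = result.sort_values(
        by=["pooled_g", "fdr", "gene"], ascending=[False, True, True], kind="mergesort"
    ).set_index("gene")
    cols = ["pooled_g", "se", "tau2", "q_stat", "n_studies", "z", "p", "fdr",
            "pooled_mean_diff_linear"]
    return result[cols]


def write_meta_table(result: pd.DataFrame, path) -> None:
    out = result.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_meta_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")
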