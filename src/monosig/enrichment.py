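"""Pre-ranked gene-set enrichment on pooled effect-size vectors.

The statistic is the classic weighted Kolmogorov–Smirnov-style running sum:
genes are ordered by effect size (descending); walking down the list, the
sum rises by ``|effect|^weight_exponent`` (normalized over the set) at
each gene-set member and falls by ``1/(N - m)`` at each non-member. The
enrichment score (ES) is the deviation of maximum magnitude. Significance
comes from gene-label permutations (random same-size sets), with the
sign-matched convention: the p-value and the normalizing mean for NES use
only permutation scores of the same sign as the observed ES.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import Signature
from .errors import ParameterError
from .meta import benjamini_hochberg


def _running_sum_es(positions: np.ndarray, weights: np.ndarray, n_genes: int) -> float:
    """ES for one gene set given sorted 0-based hit positions in a ranking
    of ``n_genes`` genes with per-gene hit weights (already exponentiated).

    Only hit positions need to be visited: between hits the running sum
    decreases linearly, so its extremes occur at a hit (upper candidate) or
    just before one (lower candidate).
    """
    m = len(positions)
    if m == n_genes:
        return 0.0  # hits exhaust the ranking; no miss mass to deviate from
    w = weights[positions]
    total = w.sum()
    if total <= 0:
        # all-zero weights inside the set: hits contribute uniformly
        w = np.ones(m)
        total = float(m)
    hit_cum = np.cumsum(w) / total
    miss_before = (positions - np.arange(m)) / (n_genes - m)
    dev_top = hit_cum - miss_before  # right after each hit
    dev_bottom = np.concatenate([[0.0], hit_cum[:-1]]) - miss_before  # just before
    # trailing misses only return toward 0, so no extra candidate is needed
    hi = dev_top.max()
    lo = dev_bottom.min()
    return float(hi if hi >= -lo else lo)


def _permutation_es(
    weights: np.ndarray, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets (gene-label permutation)."""
    n = len(weights)
    if m == n:
        return np.zeros(n_perm)
    pos = np.argpartition(rng.random((n_perm, n)), m - 1, axis=1)[:, :m]
    pos.sort(axis=1)
    w = weights[pos]
    totals = w.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] <= 0
    if degenerate.any():
        w[degenerate] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    hit_cum = np.cumsum(w, axis=1) / totals
    miss_before = (pos - np.arange(m)[None, :]) / (n - m)
    dev_top = hit_cum - miss_before
    dev_bottom = np.concatenate(
        [np.zeros((n_perm, 1)), hit_cum[:, :-1]], axis=1
    ) - miss_before
    hi = dev_top.max(axis=1)
    lo = dev_bottom.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def preranked_gsea(
    ranking,
    gene_sets,
    n_perm: int = 10000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 3,
    max_size_fraction: float = 0.5,
) -> pd.DataFrame:
    """Enrichment of each gene set in an effect-size ranking.

    Parameters
    ----------
    ranking : mapping or pandas.Series
        Gene -> effect size (e.g. pooled Hedges' g). Order of the input is
        irrelevant; genes are ranked by effect descending (ties broken by
        gene symbol for determinism).
    gene_sets : list of Signature, or mapping name -> gene list.
    n_perm : int
        Gene-label permutations for the null (same-size random sets).
    weight_exponent : float
        Exponent on ``|effect|`` for hit increments; 0 gives the unweighted
        KS statistic, 1 the classic weighted default.
    min_size, max_size_fraction :
        Sets with fewer than ``min_size`` ranked members, or more than
        ``max_size_fraction`` of the ranking, are skipped (reported in
        ``result.attrs['skipped']``).

    Returns a frame indexed by gene-set name with columns
    ``es, nes, p, fdr, size``, sorted by p then name.
    """
    if isinstance(ranking, pd.Series):
        series = ranking.astype(float)
    else:
        series = pd.Series(dict(ranking), dtype=float)
    if len(series) < 2:
        raise ParameterError("ranking must contain at least 2 genes")
    if series.isna().any():
        raise ParameterError("ranking contains NaN effects")
    if (series == 0).all():
        raise ParameterError("all effects are zero; ranking is uninformative")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")

    order = series.reset_index()
    order.columns = ["gene", "effect"]
    order = order.sort_values(by=["effect", "gene"], ascending=[False, True],
                              kind="mergesort")
    genes = order["gene"].to_numpy()
    effects = order["effect"].to_numpy(dtype=float)
    n = len(genes)
    weights = np.abs(effects) ** weight_exponent
    position = {str(g).upper(): i for i, g in enumerate(genes)}

    if isinstance(gene_sets, dict):
        sets = [(name, list(members)) for name, members in gene_sets.items()]
    else:
        sets = [(s.name, list(s.genes)) for s in gene_sets if isinstance(s, Signature)]
        if len(sets) != len(gene_sets):
            raise ParameterError("gene_sets must be Signatures or a name->genes mapping")
    if not sets:
        raise ParameterError("no gene sets given")

    rng = np.random.default_rng(seed)
    max_size = int(np.floor(max_size_fraction * n))
    rows, skipped = [], []
    perm_cache: dict[int, np.ndarray] = {}
    for name, members in sets:
        pos = np.array(
            sorted({position[g.upper()] for g in members if g.upper() in position}),
            dtype=int,
        )
        m = len(pos)
        if m < min_size or m > max_size:
            skipped.append(name)
            continue
        es = _running_sum_es(pos, weights, n)
        if m not in perm_cache:
            perm_cache[m] = _permutation_es(weights, m, n_perm, rng)
        perm = perm_cache[m]
        if es >= 0:
            same_sign = perm[perm >= 0]
            p = (1.0 + (same_sign >= es).sum()) / (1.0 + len(same_sign))
        else:
            same_sign = perm[perm < 0]
            p = (1.0 + (same_sign <= es).sum()) / (1.0 + len(same_sign))
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append({"name": name, "es": es, "nes": nes, "p": p, "size": m})

    if not rows:
        raise ParameterError(
            "every gene set was skipped (empty intersection or size limits)"
        )
    result = pd.DataFrame(rows).set_index("name")
    result["fdr"] = benjamini_hochberg(result["p"].to_numpy())
    result = result.sort_values(by=["p", "name"], kind="mergesort")
    result.attrs["skipped"] = skipped
    return result[["es", "nes", "p", "fdr", "size"]]


def write_enrichment_table(result: pd.DataFrame, path) -> None:
    out = result.copy()
    out.insert(0, "name", out.index)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
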