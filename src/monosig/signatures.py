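"""Parsimonious signature selection from meta-analysis output, plus the
published monocyte signatures bundled as a data resource.

Selection applies four rules to the per-gene pooled results: (a) rank genes
by pooled effect size, (b) keep genes up-regulated in the subset of
interest, (c) keep genes whose pooled linear-scale mean expression
difference is at least ``min_mean_diff`` (default 32 expression units,
interpreted on the linear intensity scale; configurable), (d) take the top
``top_k`` (default 10). A significance ceiling (``fdr_max``, default 0.05)
is applied alongside (b); the published procedure does not print its
cutoff, so 0.05 is the recorded default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import Signature
from .errors import ParameterError
from .simulate import CLASSICAL, INTERMEDIATE, NONCLASSICAL


@dataclass
class SelectionCriteria:
    """The 4-rule selection: direction, expression-difference floor (linear
    units), significance ceiling, and signature size."""

    direction: str = "up"
    min_mean_diff: float = 32.0
    top_k: int = 10
    fdr_max: float = 0.05

    def __post_init__(self) -> None:
        if self.direction != "up":
            raise ParameterError("only 'up' (over-expressed) selection is supported")
        if self.top_k < 1:
            raise ParameterError("top_k must be >= 1")
        if self.min_mean_diff < 0:
            raise ParameterError("min_mean_diff must be >= 0")
        if not (0 < self.fdr_max <= 1):
            raise ParameterError("fdr_max must lie in (0, 1]")


@dataclass
class SelectionOutcome:
    """A selected signature plus bookkeeping on how the filters bound."""

    signature: Signature
    shortfall: bool
    n_candidates: int
    n_pass_direction: int
    n_pass_fdr: int
    n_pass_diff: int


def select_signature(
    meta: pd.DataFrame,
    criteria: SelectionCriteria,
    subset: str,
    name: str | None = None,
) -> SelectionOutcome:
    """Apply the 4-rule selection to a meta-analysis table.

    ``meta`` is the frame returned by :func:`monosig.meta.run_meta` (indexed
    by gene, with ``pooled_g``, ``fdr`` and ``pooled_mean_diff_linear``).
    Genes are ranked by pooled_g descending (ties: smaller fdr, then gene
    symbol) and filtered to pooled_g > 0, fdr <= fdr_max and
    pooled_mean_diff_linear >= min_mean_diff; the first ``top_k`` survivors
    form the signature. Fewer survivors than ``top_k`` is flagged as a
    shortfall; zero survivors is an error naming the binding filter counts.
    """
    if meta.empty:
        raise ParameterError("meta-analysis table is empty")
    required = {"pooled_g", "fdr", "pooled_mean_diff_linear"}
    if not required <= set(meta.columns):
        raise ParameterError(f"meta table lacks columns {sorted(required - set(meta.columns))}")

    df = meta.reset_index().rename(columns={meta.index.name or "index": "gene"})
    df = df.sort_values(
        by=["pooled_g", "fdr", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    up = df["pooled_g"] > 0
    sig = df["fdr"] <= criteria.fdr_max
    diff = df["pooled_mean_diff_linear"] >= criteria.min_mean_diff
    survivors = df.loc[up & sig & diff, "gene"].tolist()
    if not survivors:
        raise ParameterError(
            "no gene survives selection for subset "
            f"{subset!r}: {int(up.sum())}/{len(df)} up-regulated, "
            f"{int((up & sig).sum())} also at FDR <= {criteria.fdr_max}, "
            f"{int((up & sig & diff).sum())} also with mean difference >= "
            f"{criteria.min_mean_diff}"
        )
    chosen = survivors[: criteria.top_k]
    signature = Signature(
        name=name or f"{subset}_top{criteria.top_k}",
        subset=subset,
        genes=chosen,
        direction="up",
    )
    return SelectionOutcome(
        signature=signature,
        shortfall=len(survivors) < criteria.top_k,
        n_candidates=len(df),
        n_pass_direction=int(up.sum()),
        n_pass_fdr=int((up & sig).sum()),
        n_pass_diff=int((up & sig & diff).sum()),
    )


def bundled_signatures() -> list[Signature]:
    """The published monocyte-subset signatures, as far as the primary text
    prints them.

    The intermediate-monocyte signature is reproduced verbatim from the
    publication (10 genes; the printed symbols ATP50 and DX39A are preserved
    with their likely-intended current symbols ATP5O and DDX39A recorded as
    aliases). The full 10-gene classical and nonclassical discovery
    signatures appear only in supplementary material that is not
    redistributed here, so those two entries are partial stand-ins carrying
    only the genes the primary text itself names: for the nonclassical
    subset the three named signature members (SIGLEC10, IER2, CTSA), and
    for the classical subset the four main-text classical-elevated surface
    markers (CSF3R, FCGR2A, CD36, IL17RA) — the latter are validated
    classical markers but are not confirmed members of the top-10 list.
    """
    return [
        Signature(
            name="classical_monocyte_markers_partial",
            subset=CLASSICAL,
            genes=["CSF3R", "FCGR2A", "CD36", "IL17RA"],
        ),
        Signature(
            name="nonclassical_monocyte_signature_partial",
            subset=NONCLASSICAL,
            genes=["SIGLEC10", "IER2", "CTSA"],
        ),
        Signature(
            name="intermediate_monocyte_signature",
            subset=INTERMEDIATE,
            genes=["ATG2A", "ATP50", "DX39A", "EVL", "GPR183", "LPCAT1",
                   "POU2F2", "TSC22D4", "ZNF14", "ARHGAP27"],
            aliases={"ATP50": "ATP5O", "DX39A": "DDX39A"},
        ),
    ]
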