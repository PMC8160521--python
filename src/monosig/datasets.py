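"""Core in-memory containers: expression datasets and gene signatures.

An :class:`ExpressionDataset` holds one study's expression matrix
(features x samples, linear-scale intensities, ``NaN`` = missing) together
with per-sample annotations. A :class:`Signature` is a named, directed list
of gene symbols for one cell subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, FormatError

#: Subset label reserved for mixed-cell (PBMC/whole-blood-like) samples.
MIXED_LABEL = "mixed"

ANNOTATION_COLUMNS = ("sample_id", "study_id", "platform_id", "subset", "disease")


@dataclass
class ExpressionDataset:
    """One study's expression matrix plus per-sample annotations.

    Parameters
    ----------
    study_id : str
        Study accession or synthetic study name.
    platform_id : str
        Measurement platform identifier.
    values : pandas.DataFrame
        Feature x sample matrix of linear-scale expression (non-negative
        where measured); ``NaN`` marks a missing measurement.
    annotations : pandas.DataFrame
        Indexed by sample id, with at least ``subset`` and ``disease``
        columns. Column order of ``values`` follows the annotation order.
    """

    study_id: str
    platform_id: str
    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ann = self.annotations
        if ann.index.has_duplicates:
            dups = ann.index[ann.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids in study {self.study_id!r}: {dups}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids in study {self.study_id!r}: {dups}")
        if self.values.shape[0] < 1:
            raise SchemaError(f"study {self.study_id!r} has no features")
        if self.values.shape[1] < 2:
            raise SchemaError(f"study {self.study_id!r} has fewer than 2 samples")
        missing = [s for s in self.values.columns if s not in ann.index]
        if missing:
            raise SchemaError(
                f"samples missing from annotation in study {self.study_id!r}: {missing}"
            )
        if "subset" not in ann.columns:
            raise SchemaError(f"annotation of study {self.study_id!r} lacks a 'subset' column")
        blank = ann.loc[list(self.values.columns), "subset"].isna()
        if blank.any():
            raise SchemaError(
                f"samples without subset label in study {self.study_id!r}: "
                f"{list(blank.index[blank])}"
            )
        # keep matrix columns in annotation order
        order = [s for s in ann.index if s in self.values.columns]
        self.values = self.values.loc[:, order]

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def subset_labels(self) -> pd.Series:
        """Per-sample subset label, aligned to the matrix columns."""
        return self.annotations.loc[list(self.values.columns), "subset"]

    def sorted_sample_ids(self) -> list[str]:
        """Samples carrying a sorted-subset label (i.e. not ``mixed``)."""
        lab = self.subset_labels()
        return list(lab.index[lab != MIXED_LABEL])

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        """Copy of this dataset with a replaced matrix (same annotations)."""
        return ExpressionDataset(
            study_id=self.study_id,
            platform_id=self.platform_id,
            values=values,
            annotations=self.annotations.copy(),
        )

    def log2_values(self, floor: float = 1e-12) -> pd.DataFrame:
        """log2 of the matrix, flooring non-positive entries; NaN preserved."""
        return np.log2(self.values.clip(lower=floor))


@dataclass
class Signature:
    """A named, directed gene list for one cell subset.

    Only over-expressed ("up") signatures exist in this framework: the
    selection procedure keeps genes elevated in the subset of interest.
    ``aliases`` maps a published symbol to a corrected/current symbol where
    the published spelling is a likely typo.
    """

    name: str
    subset: str
    genes: list[str]
    direction: str = "up"
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"signature {self.name!r} has duplicate genes")
        if self.direction != "up":
            raise FormatError(
                f"signature {self.name!r}: direction must be 'up', got {self.direction!r}"
            )
        for g in self.genes:
            if not g or any(c in g for c in "\t\n\r"):
                raise FormatError(
                    f"signature {self.name!r}: gene symbol {g!r} is empty or contains "
                    "whitespace control characters"
                )
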