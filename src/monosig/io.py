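"""Text-format readers and writers, plus cross-study gene alignment.

Formats (all UTF-8, LF, tab-separated unless noted):

* expression matrix: first column = feature id, header = sample ids;
  cells are linear-scale intensities, ``NA``/empty = missing;
* annotation table: columns ``sample_id, study_id, platform_id, subset,
  disease`` (extra columns preserved);
* probe map: two columns ``probe_id, gene_symbol`` (one line per pair);
* signatures: GMT (name, description, genes...) and JSON;
* scores: TSV with one row per sample.

Readers validate structure and raise :class:`~monosig.errors.SchemaError` /
:class:`~monosig.errors.ParseError` rather than silently repairing input.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ANNOTATION_COLUMNS, ExpressionDataset, Signature
from .errors import AlignmentError, FormatError, ParseError, SchemaError

_NA_STRINGS = {"", "NA", "NaN", "nan", "null"}


# ---------------------------------------------------------------------------
# expression matrices + annotations
# ---------------------------------------------------------------------------

def read_expression_dataset(matrix_path, annotation_path) -> ExpressionDataset:
    """Read one study from a matrix TSV and an annotation TSV.

    The annotation must cover every matrix column; matrix columns are
    reordered to the annotation order. Cells equal to ``NA`` (or empty) are
    stored as missing; any other non-numeric cell is a parse error reported
    with its (feature, sample) coordinates.
    """
    matrix_path, annotation_path = Path(matrix_path), Path(annotation_path)
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise SchemaError(f"{annotation_path}: missing annotation columns {missing_cols}")
    if ann["sample_id"].duplicated().any():
        dups = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{annotation_path}: duplicate sample ids {dups}")
    ann = ann.set_index("sample_id")

    with open(matrix_path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows) < 2:
        raise ParseError(f"{matrix_path}: empty or header-only matrix")
    header = rows[0]
    sample_ids = header[1:]
    width = len(header)
    data: dict[str, list[float]] = {}
    features: list[str] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{matrix_path}:{i}: row has {len(row)} fields, expected {width} "
                "(truncated or ragged file)"
            )
        feat, cells = row[0], row[1:]
        parsed = []
        for j, cell in enumerate(cells):
            if cell.strip() in _NA_STRINGS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{matrix_path}: non-numeric value {cell!r} at feature "
                    f"{feat!r}, sample {sample_ids[j]!r}"
                ) from None
        features.append(feat)
        data[feat] = parsed
    values = pd.DataFrame.from_dict(data, orient="index", columns=sample_ids).loc[features]

    not_annotated = [s for s in sample_ids if s not in ann.index]
    if not_annotated:
        raise SchemaError(
            f"{annotation_path}: annotation missing matrix samples {not_annotated}"
        )
    ann = ann.loc[sample_ids]

    study_ids = ann["study_id"].unique()
    platform_ids = ann["platform_id"].unique()
    return ExpressionDataset(
        study_id=str(study_ids[0]) if len(study_ids) == 1 else "multi",
        platform_id=str(platform_ids[0]) if len(platform_ids) == 1 else "multi",
        values=values,
        annotations=ann,
    )


def write_expression_dataset(dataset: ExpressionDataset, matrix_path, annotation_path) -> None:
    """Write a dataset as matrix TSV + annotation TSV (round-trips with
    :func:`read_expression_dataset`)."""
    values = dataset.values
    with open(matrix_path, "w", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, values.columns)) + "\n")
        for feat, row in values.iterrows():
            cells = ["NA" if pd.isna(v) else format(v, ".10g") for v in row]
            fh.write(str(feat) + "\t" + "\t".join(cells) + "\n")
    ann = dataset.annotations.loc[list(values.columns)].copy()
    ann.insert(0, "sample_id", ann.index)
    if "study_id" not in ann.columns:
        ann["study_id"] = dataset.study_id
    if "platform_id" not in ann.columns:
        ann["platform_id"] = dataset.platform_id
    cols = [c for c in ANNOTATION_COLUMNS if c in ann.columns]
    cols += [c for c in ann.columns if c not in cols]
    ann[cols].to_csv(annotation_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# probe maps
# ---------------------------------------------------------------------------

def read_probe_map(path) -> pd.DataFrame:
    """Read a two-column probe->gene TSV into a (probe_id, gene_symbol) frame.

    Many-to-one and one-to-many mappings are allowed; a probe mapping to k
    genes appears on k lines. Empty gene symbols are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise SchemaError(f"{path}: probe map must have exactly 2 columns")
    df.columns = ["probe_id", "gene_symbol"]
    if df["gene_symbol"].isna().any() or (df["gene_symbol"].str.strip() == "").any():
        raise SchemaError(f"{path}: probe map contains empty gene symbols")
    return df.drop_duplicates()


# ---------------------------------------------------------------------------
# signatures (GMT + JSON)
# ---------------------------------------------------------------------------

def write_signature_gmt(signatures: list[Signature], path) -> None:
    """Write signatures in GMT: one line per set — name, description, genes."""
    if not signatures:
        raise FormatError("cannot write an empty signature list")
    with open(path, "w", newline="\n") as fh:
        for sig in signatures:
            for g in sig.genes:
                if "\t" in g:
                    raise FormatError(f"gene symbol {g!r} contains a tab")
            desc = f"subset={sig.subset};direction={sig.direction}"
            fh.write("\t".join([sig.name, desc] + list(sig.genes)) + "\n")


def read_signature_gmt(path) -> list[Signature]:
    """Read a GMT file into signatures; the description field's
    ``subset=...`` tag is recovered when present."""
    sigs = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{i}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            subset, direction = name, "up"
            for token in desc.split(";"):
                if token.startswith("subset="):
                    subset = token[len("subset="):]
                elif token.startswith("direction="):
                    direction = token[len("direction="):]
            sigs.append(Signature(name=name, subset=subset, genes=genes, direction=direction))
    if not sigs:
        raise ParseError(f"{path}: no gene sets found")
    return sigs


def write_signature_json(signatures: list[Signature], path) -> None:
    if not signatures:
        raise FormatError("cannot write an empty signature list")
    payload = [
        {
            "name": s.name,
            "subset": s.subset,
            "direction": s.direction,
            "genes": list(s.genes),
            "aliases": dict(s.aliases),
        }
        for s in signatures
    ]
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_signature_json(path) -> list[Signature]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Signature(
            name=d["name"],
            subset=d["subset"],
            genes=list(d["genes"]),
            direction=d.get("direction", "up"),
            aliases=dict(d.get("aliases", {})),
        )
        for d in payload
    ]


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a per-sample score table (index = sample id) as TSV."""
    out = scores.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: score table lacks a sample_id column")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# gene alignment across studies
# ---------------------------------------------------------------------------

def align_genes(
    datasets: list[ExpressionDataset], mode: str = "union"
) -> tuple[list[ExpressionDataset], pd.Series]:
    """Restrict all studies to a shared gene space.

    In ``union`` mode every dataset is reindexed on the union of gene ids;
    genes a study does not measure become missing (``NaN``) rows — they are
    never imputed and are skipped by downstream effect-size computation.
    In ``intersection`` mode only genes measured by every study are kept.

    Returns the aligned datasets and a per-gene study-coverage count.
    """
    if not datasets:
        raise AlignmentError("align_genes requires at least one dataset")
    if mode not in ("union", "intersection"):
        raise AlignmentError(f"unknown alignment mode {mode!r}")
    gene_sets = [set(d.values.index) for d in datasets]
    union: list[str] = []
    seen: set[str] = set()
    for d in datasets:  # stable, first-seen order
        for g in d.values.index:
            if g not in seen:
                seen.add(g)
                union.append(g)
    coverage = pd.Series(
        {g: sum(g in s for s in gene_sets) for g in union}, name="n_studies"
    ).loc[union]
    if mode == "intersection":
        keep = [g for g in union if coverage[g] == len(datasets)]
        if not keep:
            raise AlignmentError("gene intersection across studies is empty")
        aligned = [d.with_values(d.values.loc[keep]) for d in datasets]
        return aligned, coverage.loc[keep]
    aligned = [d.with_values(d.values.reindex(union)) for d in datasets]
    return aligned, coverage
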