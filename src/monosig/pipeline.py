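"""End-to-end orchestration: simulate -> normalize -> meta -> select ->
score -> evaluate -> enrich, driven by one YAML-loadable config.

Each enabled stage runs in a fixed order, writes its outputs under
``out_dir``, and registers them in a JSON manifest carrying SHA-256 hashes
and every seed used — rerunning an identical config reproduces identical
outputs byte for byte (no timestamps enter any output). A stage failure
aborts the run with the stage named; files the failing stage had already
written are renamed with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as msio
from .datasets import ExpressionDataset
from .errors import MonosigError, ParameterError
from .meta import run_meta, write_meta_table
from .normalize import NormalizationReport, conormalize, quantile_normalize
from .enrichment import preranked_gsea, write_enrichment_table
from .scoring import auroc, ordering_check, score_table
from .signatures import SelectionCriteria, select_signature
from .simulate import (
    CLASSICAL,
    NONCLASSICAL,
    SimulationConfig,
    SimulationTruth,
    simulate_sorted_studies,
)

log = logging.getLogger("monosig")

STAGE_ORDER = ("simulate", "normalize", "meta", "select", "score", "evaluate", "enrich")


@dataclass
class PipelineConfig:
    out_dir: str = "monosig_out"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    subsets: list[str] = field(default_factory=lambda: [CLASSICAL, NONCLASSICAL])
    min_studies: int = 1
    score_floor: float = 1.0
    min_coverage: float = 0.5
    enrichment_gmt: str | None = None  # None -> use planted marker sets as gene sets
    enrichment_n_perm: int = 1000
    enrichment_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ParameterError(f"unknown pipeline stages {unknown}; valid: {STAGE_ORDER}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        sel = SelectionCriteria(**raw.pop("selection", {}))
        return cls(simulation=sim, selection=sel, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.datasets: list[ExpressionDataset] = []
        self.truth: SimulationTruth | None = None
        self.meta_tables: dict[str, object] = {}
        self.signatures = []
        self.scores = None
        self.manifest: dict = {"stages": [], "files": {}, "seeds": {}}
        self._stage_files: list[Path] = []

    def register(self, path: Path) -> None:
        self._stage_files.append(path)

    def finish_stage(self, name: str) -> None:
        for p in self._stage_files:
            self.manifest["files"][str(p.relative_to(self.out))] = _sha256(p)
        self.manifest["stages"].append(name)
        self._stage_files = []

    def mark_partial(self) -> None:
        for p in self._stage_files:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    run.datasets, run.truth = simulate_sorted_studies(cfg.simulation)
    for ds in run.datasets:
        mpath = run.out / f"{ds.study_id}_matrix.tsv"
        apath = run.out / f"{ds.study_id}_annotations.tsv"
        msio.write_expression_dataset(ds, mpath, apath)
        run.register(mpath)
        run.register(apath)
    tpath = run.out / "truth.json"
    run.truth.to_json(tpath)
    run.register(tpath)
    run.manifest["seeds"]["simulation"] = cfg.simulation.seed


def _stage_normalize(run: _Run) -> None:
    report = NormalizationReport()
    normalized = [quantile_normalize(ds, report) for ds in run.datasets]
    aligned, coverage = msio.align_genes(normalized, mode="union")
    run.datasets = conormalize(aligned, report)
    for ds in run.datasets:
        mpath = run.out / f"{ds.study_id}_normalized.tsv"
        apath = run.out / f"{ds.study_id}_normalized_annotations.tsv"
        msio.write_expression_dataset(ds, mpath, apath)
        run.register(mpath)
        run.register(apath)
    rpath = run.out / "normalization_report.json"
    with open(rpath, "w", newline="\n") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    run.register(rpath)


def _stage_meta(run: _Run) -> None:
    for subset in run.config.subsets:
        table = run_meta(run.datasets, subset, min_studies=run.config.min_studies)
        run.meta_tables[subset] = table
        path = run.out / f"meta_{subset}.tsv"
        write_meta_table(table, path)
        run.register(path)


def _stage_select(run: _Run) -> None:
    outcomes = {}
    for subset, table in run.meta_tables.items():
        outcome = select_signature(table, run.config.selection, subset)
        run.signatures.append(outcome.signature)
        outcomes[subset] = {
            "genes": outcome.signature.genes,
            "shortfall": outcome.shortfall,
            "n_pass_direction": outcome.n_pass_direction,
            "n_pass_fdr": outcome.n_pass_fdr,
            "n_pass_diff": outcome.n_pass_diff,
        }
    gmt = run.out / "signatures.gmt"
    jsn = run.out / "signatures.json"
    msio.write_signature_gmt(run.signatures, gmt)
    msio.write_signature_json(run.signatures, jsn)
    rpath = run.out / "selection_report.json"
    with open(rpath, "w", newline="\n") as fh:
        json.dump(outcomes, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for p in (gmt, jsn, rpath):
        run.register(p)


def _stage_score(run: _Run) -> None:
    run.scores = score_table(
        run.datasets, run.signatures,
        floor=run.config.score_floor, min_coverage=run.config.min_coverage,
    )
    path = run.out / "scores.tsv"
    msio.write_score_table(run.scores, path)
    run.register(path)


def _stage_evaluate(run: _Run) -> None:
    evaluation: dict = {"auroc": {}, "recovery": {}}
    for sig in run.signatures:
        labels = (run.scores["subset"] == sig.subset).astype(int)
        roc = auroc(run.scores[sig.name].to_numpy(), labels.to_numpy())
        evaluation["auroc"][sig.name] = {
            "auroc": roc.auroc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        }
        if run.truth is not None and sig.subset in run.truth.marker_genes_by_subset:
            planted = set(run.truth.marker_genes_by_subset[sig.subset])
            evaluation["recovery"][sig.name] = {
                "n_planted": len(planted),
                "n_recovered": len(planted & set(sig.genes)),
            }
    if {"classical", "intermediate", "nonclassical"} <= set(run.scores["subset"].unique()):
        for sig in run.signatures:
            ok, means = ordering_check(run.scores, sig.name)
            evaluation.setdefault("intermediate_ordering", {})[sig.name] = {
                "between": ok, "means": means,
            }
    path = run.out / "evaluation.json"
    with open(path, "w", newline="\n") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)
        fh.write("\n")
    run.register(path)


def _stage_enrich(run: _Run) -> None:
    cfg = run.config
    if cfg.enrichment_gmt:
        gene_sets = msio.read_signature_gmt(cfg.enrichment_gmt)
    elif run.truth is not None and run.truth.marker_genes_by_subset:
        gene_sets = {
            f"planted_{subset}_markers": genes
            for subset, genes in run.truth.marker_genes_by_subset.items()
        }
    else:
        raise ParameterError("enrich stage needs enrichment_gmt or simulated truth")
    for subset, table in run.meta_tables.items():
        ranking = table["pooled_g"]
        result = preranked_gsea(
            ranking, gene_sets, n_perm=cfg.enrichment_n_perm, seed=cfg.enrichment_seed
        )
        path = run.out / f"enrichment_{subset}.tsv"
        write_enrichment_table(result, path)
        run.register(path)
    run.manifest["seeds"]["enrichment"] = cfg.enrichment_seed


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "meta": _stage_meta,
    "select": _stage_select,
    "score": _stage_score,
    "evaluate": _stage_evaluate,
    "enrich": _stage_enrich,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order and return the manifest.

    The manifest (also written to ``out_dir/manifest.json``) lists every
    output file with its SHA-256, the seeds used, and the full config; it is
    byte-identical across reruns of the same config.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    run = _Run(config)
    run.manifest["config"] = config.to_dict()
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    for name in enabled:
        log.info("stage %s: starting", name)
        try:
            _STAGE_FUNCS[name](run)
        except Exception as exc:
            run.mark_partial()
            raise MonosigError(f"pipeline stage {name!r} failed: {exc}") from exc
        run.finish_stage(name)
        log.info("stage %s: done", name)
    manifest_path = run.out / "manifest.json"
    with open(manifest_path, "w", newline="\n") as fh:
        json.dump(run.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return run.manifest


def load_and_run(config_path) -> dict:
    return run_pipeline(PipelineConfig.from_yaml(config_path))
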