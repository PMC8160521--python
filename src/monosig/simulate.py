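"""Synthetic multi-study sorted-monocyte compendia with known ground truth.

The generator emulates the structure of a heterogeneous public-data
compendium: several independent studies, each profiling sorted classical and
nonclassical monocytes (optionally an intermediate subset modeled as a
transitional mixture), with

* a log2-normal expression model (Gaussian on the log2 scale, stored as
  linear intensities, matching microarray semantics),
* subset-specific marker genes whose log2 means are shifted by
  ``planted_effect_size * within_sd`` so the realized standardized mean
  difference (Hedges' g) targets the planted value,
* an additive per-study batch shift on the log2 scale, shared by all genes
  and subsets of the study (removable by co-normalization),
* gene-wise uniform dropout per study (platform coverage differences),
* mixed-cell samples built as fraction-weighted convex combinations of
  subset mean profiles on the linear scale.

A single global seed feeds a hierarchical per-study stream, so studies are
independent yet the whole compendium is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, MIXED_LABEL
from .errors import AlignmentError, ParameterError

CLASSICAL = "classical"
INTERMEDIATE = "intermediate"
NONCLASSICAL = "nonclassical"


@dataclass
class SimulationConfig:
    """Parameters of the sorted-subset compendium generator.

    ``within_sd`` is the within-group standard deviation on the log2 scale;
    marker genes are shifted by ``planted_effect_size * within_sd`` log2
    units in their subset, so the realized Hedges' g targets
    ``planted_effect_size``. ``batch_sd`` (log2 units) controls
    study-to-study location heterogeneity; public compendia do not pin this
    quantity down, so the 0.5 default is a free choice of plausible
    magnitude.
    """

    n_studies: int = 6
    samples_per_subset_per_study: int = 10
    n_genes: int = 1000
    n_markers_per_subset: int = 10
    planted_effect_size: float = 2.0
    baseline_mean: float = 256.0  # linear expression units
    baseline_sd: float = 64.0  # linear units, spread of per-gene baselines
    within_sd: float = 0.5  # log2 units, within-group noise
    batch_sd: float = 0.5  # log2 units, per-study additive shift
    dropout_fraction: float = 0.1
    include_intermediate: bool = False
    intermediate_lambda: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_studies", "samples_per_subset_per_study", "n_genes",
                     "n_markers_per_subset"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        for name in ("baseline_sd", "within_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.baseline_mean <= 0:
            raise ParameterError("baseline_mean must be > 0")
        if not (0 <= self.dropout_fraction < 1):
            raise ParameterError("dropout_fraction must lie in [0, 1)")
        if not (0 <= self.intermediate_lambda <= 1):
            raise ParameterError("intermediate_lambda must lie in [0, 1]")
        n_subsets = 3 if self.include_intermediate else 2
        if self.n_markers_per_subset * n_subsets > self.n_genes:
            raise ParameterError(
                "n_markers_per_subset x number of subsets exceeds n_genes"
            )

    @property
    def subsets(self) -> list[str]:
        if self.include_intermediate:
            return [CLASSICAL, INTERMEDIATE, NONCLASSICAL]
        return [CLASSICAL, NONCLASSICAL]


@dataclass
class SimulationTruth:
    """Ground truth of one simulation: planted markers, planted effect
    sizes, true mixture fractions, and the seed that produced them."""

    marker_genes_by_subset: dict[str, list[str]] = field(default_factory=dict)
    planted_effect_sizes: dict[str, float] = field(default_factory=dict)
    mixture_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        all_markers: set[str] = set()
        for subset, genes in self.marker_genes_by_subset.items():
            overlap = all_markers & set(genes)
            if overlap:
                raise ParameterError(
                    f"marker sets not disjoint: {sorted(overlap)} reused by {subset!r}"
                )
            all_markers |= set(genes)
        for sid, fr in self.mixture_fractions.items():
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"mixture fractions of sample {sid!r} sum to {total}, not 1"
                )

    def to_json(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{str(i).zfill(width)}" for i in range(1, n + 1)]


def simulate_sorted_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], SimulationTruth]:
    """Generate ``config.n_studies`` independent sorted-subset studies.

    Classical and nonclassical subsets each receive
    ``n_markers_per_subset`` disjoint marker genes over-expressed by
    ``planted_effect_size`` standard deviations (log2 scale). When
    ``include_intermediate`` is set, a third subset is added whose per-gene
    log2 mean is the ``intermediate_lambda``-weighted mixture of the two
    pure profiles (a transitional state, without markers of its own).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    global_rng = np.random.default_rng(root.spawn(1)[0])
    study_seeds = root.spawn(config.n_studies)

    genes = _gene_ids(config.n_genes)
    # per-gene baseline linear means, clipped to stay meaningfully positive
    baseline_linear = np.clip(
        global_rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes),
        config.baseline_mean / 16.0,
        None,
    )
    baseline_log2 = np.log2(baseline_linear)

    marker_subsets = [CLASSICAL, NONCLASSICAL]
    n_mark = config.n_markers_per_subset
    marker_idx = global_rng.choice(
        config.n_genes, size=n_mark * len(marker_subsets), replace=False
    )
    markers = {
        subset: sorted(genes[i] for i in marker_idx[k * n_mark:(k + 1) * n_mark])
        for k, subset in enumerate(marker_subsets)
    }
    shift = config.planted_effect_size * config.within_sd
    # subset -> per-gene log2 mean profile
    mean_log2 = {s: baseline_log2.copy() for s in marker_subsets}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for subset in marker_subsets:
        for g in markers[subset]:
            mean_log2[subset][gene_pos[g]] += shift
    if config.include_intermediate:
        lam = config.intermediate_lambda
        mean_log2[INTERMEDIATE] = (
            lam * mean_log2[CLASSICAL] + (1 - lam) * mean_log2[NONCLASSICAL]
        )

    datasets = []
    n_per = config.samples_per_subset_per_study
    for s, seed_seq in enumerate(study_seeds, start=1):
        rng = np.random.default_rng(seed_seq)
        study_id = f"study{s:02d}"
        batch = rng.normal(0.0, config.batch_sd) if config.batch_sd > 0 else 0.0
        cols, labels, blocks = [], [], []
        for subset in config.subsets:
            noise = rng.normal(0.0, config.within_sd, size=(config.n_genes, n_per))
            log2_vals = mean_log2[subset][:, None] + batch + noise
            blocks.append(log2_vals)
            cols += [f"{study_id}_{subset}_{i + 1:02d}" for i in range(n_per)]
            labels += [subset] * n_per
        values = pd.DataFrame(
            np.power(2.0, np.concatenate(blocks, axis=1)), index=genes, columns=cols
        )
        n_drop = int(round(config.dropout_fraction * config.n_genes))
        if n_drop:
            dropped = rng.choice(config.n_genes, size=n_drop, replace=False)
            values = values.drop(index=[genes[i] for i in dropped])
        annotations = pd.DataFrame(
            {
                "study_id": study_id,
                "platform_id": f"platform{(s - 1) % 4 + 1}",
                "subset": labels,
                "disease": "healthy",
            },
            index=pd.Index(cols, name="sample_id"),
        )
        datasets.append(
            ExpressionDataset(study_id, annotations["platform_id"].iloc[0], values, annotations)
        )

    truth = SimulationTruth(
        marker_genes_by_subset=markers,
        planted_effect_sizes={
            g: config.planted_effect_size for subset in markers for g in markers[subset]
        },
        mixture_fractions={},
        seed=config.seed,
    )
    return datasets, truth


def mean_subset_profiles(datasets: list[ExpressionDataset]) -> dict[str, pd.Series]:
    """Per-subset mean linear expression profile pooled across studies.

    Genes a study does not measure are excluded pairwise. Mixed samples are
    ignored. Useful as input to the mixture and intermediate simulators.
    """
    frames: dict[str, list[pd.DataFrame]] = {}
    for ds in datasets:
        lab = ds.subset_labels()
        for subset in lab.unique():
            if subset == MIXED_LABEL:
                continue
            frames.setdefault(subset, []).append(ds.values.loc[:, lab.index[lab == subset]])
    return {
        subset: pd.concat(parts, axis=1).mean(axis=1, skipna=True)
        for subset, parts in frames.items()
    }


def simulate_intermediate_profiles(
    classical_mean_profile: pd.Series,
    nonclassical_mean_profile: pd.Series,
    lam: float,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    study_id: str = "intermediate_sim",
) -> ExpressionDataset:
    """Samples of a transitional subset: per-gene log2 mean is the
    ``lam``-weighted mixture of the classical and nonclassical log2
    profiles, plus Gaussian log2 noise of sd ``noise_sd``.

    ``lam=1`` reproduces the classical profile, ``lam=0`` the nonclassical
    one. Profiles are linear-scale per-gene means sharing one gene index.
    """
    if not (0 <= lam <= 1):
        raise ParameterError(f"lambda must lie in [0, 1], got {lam}")
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if set(classical_mean_profile.index) != set(nonclassical_mean_profile.index):
        raise AlignmentError("classical and nonclassical profiles have different gene indices")
    nc = nonclassical_mean_profile.loc[classical_mean_profile.index]
    log2_mean = lam * np.log2(classical_mean_profile.to_numpy(float)) + (1 - lam) * np.log2(
        nc.to_numpy(float)
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(len(log2_mean), n_samples))
    else:
        noise = np.zeros((len(log2_mean), n_samples))
    cols = [f"{study_id}_{INTERMEDIATE}_{i + 1:02d}" for i in range(n_samples)]
    values = pd.DataFrame(
        np.power(2.0, log2_mean[:, None] + noise),
        index=classical_mean_profile.index,
        columns=cols,
    )
    annotations = pd.DataFrame(
        {"study_id": study_id, "platform_id": "synthetic", "subset": INTERMEDIATE,
         "disease": "healthy"},
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionDataset(study_id, "synthetic", values, annotations)


def simulate_mixtures(
    subset_mean_profiles: dict[str, pd.Series],
    n_samples: int,
    dirichlet_alpha,
    noise_sd: float = 0.0,
    seed: int = 0,
    study_id: str = "mixture_sim",
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Mixed-cell (PBMC-like) samples with known subset fractions.

    Each sample's linear-scale expression is the fraction-weighted convex
    combination of the subset mean profiles; fractions are drawn from a
    Dirichlet with concentration ``dirichlet_alpha`` (one entry per subset)
    and recorded in the returned truth. Multiplicative log-normal noise of
    log2-sd ``noise_sd`` is applied when nonzero.
    """
    subsets = list(subset_mean_profiles)
    if not subsets:
        raise ParameterError("subset_mean_profiles is empty")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.ndim != 1 or len(alpha) != len(subsets):
        raise ParameterError(
            f"dirichlet_alpha has {alpha.size} entries for {len(subsets)} subsets"
        )
    if np.any(alpha <= 0):
        raise ParameterError("dirichlet_alpha entries must be > 0")
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    index = subset_mean_profiles[subsets[0]].index
    for s in subsets[1:]:
        if set(subset_mean_profiles[s].index) != set(index):
            raise AlignmentError(f"profile of subset {s!r} has a different gene index")
    profiles = np.column_stack(
        [subset_mean_profiles[s].loc[index].to_numpy(float) for s in subsets]
    )  # genes x subsets

    rng = np.random.default_rng(seed)
    fractions = rng.dirichlet(alpha, size=n_samples)  # samples x subsets
    linear = profiles @ fractions.T  # genes x samples
    if noise_sd > 0:
        linear = linear * np.power(2.0, rng.normal(0.0, noise_sd, size=linear.shape))
    cols = [f"{study_id}_mix_{i + 1:02d}" for i in range(n_samples)]
    values = pd.DataFrame(linear, index=index, columns=cols)
    annotations = pd.DataFrame(
        {"study_id": study_id, "platform_id": "synthetic", "subset": MIXED_LABEL,
         "disease": "healthy"},
        index=pd.Index(cols, name="sample_id"),
    )
    truth = SimulationTruth(
        marker_genes_by_subset={},
        planted_effect_sizes={},
        mixture_fractions={
            sid: {s: float(f) for s, f in zip(subsets, frac)}
            for sid, frac in zip(cols, fractions)
        },
        seed=seed,
    )
    return ExpressionDataset(study_id, "synthetic", values, annotations), truth
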