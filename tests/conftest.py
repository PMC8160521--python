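import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from monosig import ExpressionDataset, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(
    values: dict[str, list[float]],
    subsets: list[str],
    study_id: str = "studyA",
    features: list[str] | None = None,
) -> ExpressionDataset:
    """Build a small dataset; `values` maps sample id -> column of values."""
    samples = list(values)
    n_feat = len(next(iter(values.values())))
    feats = features or [f"G{i}" for i in range(1, n_feat + 1)]
    mat = pd.DataFrame({s: values[s] for s in samples}, index=feats, dtype=float)
    ann = pd.DataFrame(
        {
            "study_id": study_id,
            "platform_id": "plat1",
            "subset": subsets,
            "disease": "healthy",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionDataset(study_id, "plat1", mat, ann)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    return make_dataset(
        {"s1": [5, 2, 3], "s2": [4, 1, 8], "s3": [6, 3, 9], "s4": [7, 2, 4]},
        subsets=["classical", "classical", "nonclassical", "nonclassical"],
    )


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A fast configuration for unit tests (not the study conditions)."""
    return SimulationConfig(
        n_studies=3,
        samples_per_subset_per_study=6,
        n_genes=120,
        n_markers_per_subset=5,
        planted_effect_size=2.0,
        dropout_fraction=0.1,
        seed=11,
    )
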