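import numpy as np
import pandas as pd
import pytest

from thydex import SimulationConfig, generate_dataset, run_pipeline
from thydex.io import ExpressionMatrix


SMALL_CLASS_COUNTS = {
    "thyroid_identity": 20,
    "shared_developmental": 20,
    "pattern_I": 8,
    "pattern_II": 8,
    "pattern_III": 8,
    "pattern_IV": 8,
    "at_specific": 8,
    "et_specific": 8,
}


@pytest.fixture
def small_config():
    """A fast, small simulation used by unit tests."""
    return SimulationConfig(n_genes=500, class_counts=dict(SMALL_CLASS_COUNTS), seed=11)


@pytest.fixture
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study conditions (shared)."""
    return run_pipeline(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_run():
    """Full-size pipeline run with no planted effects."""
    cfg = SimulationConfig(seed=7, class_counts={c: 0 for c in SMALL_CLASS_COUNTS})
    return run_pipeline(cfg)


def toy_matrix(values, feature_ids=None, sample_ids=None, level="probe"):
    arr = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=feature_ids, columns=sample_ids), level=level
    )
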