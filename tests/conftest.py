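import numpy as np
import pytest

from dfctest import (
    ExpressionDataset,
    FlatProfile,
    SimulationConfig,
    estimate_null_model,
    generate_dataset,
    summarize_features,
)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Two features, two samples per class, hand-checkable numbers."""
    return ExpressionDataset(
        values=np.array([[2.0, 4.0, 1.0, 3.0], [5.0, 5.0, 5.0, 5.0]]),
        feature_ids=np.array(["f1", "f2"], dtype=object),
        class_labels=np.array([1, 1, 2, 2]),
    )


@pytest.fixture(scope="session")
def null_config() -> SimulationConfig:
    return SimulationConfig(
        n_features=5000, n1=10, n2=10, pi=0.0, profile=FlatProfile(v=0.25), seed=42
    )


@pytest.fixture(scope="session")
def null_dataset(null_config):
    return generate_dataset(null_config)


@pytest.fixture(scope="session")
def null_summaries(null_dataset):
    dataset, _ = null_dataset
    return summarize_features(dataset)


@pytest.fixture(scope="session")
def null_model_fitted(null_summaries):
    return estimate_null_model(null_summaries)


@pytest.fixture(scope="session")
def de_dataset():
    """Dataset with 2% planted DEGs on a flat variance profile."""
    config = SimulationConfig(
        n_features=5000, n1=10, n2=10, pi=0.02, profile=FlatProfile(v=0.25), seed=7
    )
    return generate_dataset(config)
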