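import numpy as np
import pytest

from eegemotion.data_io import FeatureTable
from eegemotion.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 rows, 2 features, one label of each class."""
    return FeatureTable(
        values=[[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]],
        feature_names=["a", "b"],
        labels=[1, 2, 0],
    )


@pytest.fixture
def random_table() -> FeatureTable:
    rng = np.random.default_rng(42)
    n, p = 50, 5
    return FeatureTable(rng.standard_normal((n, p)),
                        [f"f{j}" for j in range(p)],
                        rng.integers(0, 3, size=n))


@pytest.fixture(scope="session")
def separable_small() -> FeatureTable:
    """Well-separated 3-class data at desk-test scale."""
    return generate_dataset(GeneratorConfig(
        n_per_class=60, p=32, separability=6.0, seed=1))


@pytest.fixture(scope="session")
def null_small() -> FeatureTable:
    """Identical class-conditional distributions (separability 0)."""
    return generate_dataset(GeneratorConfig(
        n_per_class=60, p=32, separability=0.0, seed=1))


def nearest_centroid_accuracy(train: FeatureTable, test: FeatureTable) -> float:
    """Independent sanity oracle: classify by closest training class mean."""
    centroids = np.stack([train.values[train.labels == k].mean(axis=0)
                          for k in range(3)])
    d2 = ((test.values[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    return float((np.argmin(d2, axis=1) == test.labels).mean())
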