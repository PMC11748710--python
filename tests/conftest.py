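import numpy as np
import pandas as pd
import pytest

from nucgrade import FeatureTable, HistogramConfig, SimConfig, default_profiles
from nucgrade.synthetic import generate_dataset, generate_feature_table


@pytest.fixture
def default_config() -> HistogramConfig:
    return HistogramConfig()


@pytest.fixture(scope="session")
def small_images():
    """15 synthetic images (5 per class), shared across tests."""
    return generate_dataset(SimConfig(n_per_class=5, seed=7), default_profiles())


@pytest.fixture(scope="session")
def small_table() -> FeatureTable:
    """Feature table for 30/class default-profile images."""
    return generate_feature_table(SimConfig(n_per_class=30, seed=11))


def make_gaussian_table(n_per_class: int, separation: float, seed: int,
                        n_noise: int = 2) -> FeatureTable:
    """3-class Gaussian feature clusters with controllable mean separation
    (in within-class SD units) plus pure-noise columns.

    Class means sit at the vertices of an equilateral triangle in the
    2-D signal plane, so every pair of classes is `separation` apart and
    no class lies between the other two (collinear means would mask the
    middle class under one-vs-all linear scoring).
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2, 3], n_per_class)
    vertices = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    centers = separation * vertices[y - 1]
    cols = {
        "sig1": centers[:, 0] + rng.normal(0, 1, y.size),
        "sig2": centers[:, 1] + rng.normal(0, 1, y.size),
    }
    for k in range(n_noise):
        cols[f"noise{k + 1}"] = rng.normal(0, 1, y.size)
    return FeatureTable(pd.DataFrame(cols), y)
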