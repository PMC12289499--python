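import numpy as np
import pandas as pd
import pytest

from radscore.io import FeatureTable
from radscore.synthetic import SimulationConfig, generate_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """30 samples x 6 features, balanced labels, one informative feature."""
    n = 30
    labels = np.array([1, 0] * (n // 2))
    x = rng.standard_normal((n, 6))
    x[labels == 1, 0] += 2.0
    names = [f"firstorder_feat{i:02d}" for i in range(1, 7)]
    return FeatureTable([f"S{i:03d}" for i in range(n)], labels,
                        pd.DataFrame(x, columns=names))


@pytest.fixture
def default_cohort():
    table, truth = generate_feature_table(SimulationConfig(seed=42), "derivation")
    return table, truth


def make_small_config(**overrides) -> SimulationConfig:
    """20-feature simulation used by the loop-scale tests."""
    base = dict(
        n_features=20,
        feature_class_counts={"shape": 3, "firstorder": 3, "glcm": 4, "glrlm": 3,
                              "glszm": 3, "gldm": 3, "ngtdm": 1},
        n_informative=3, effect_sizes=(1.0, 1.0, 1.0),
        n_redundant_pairs=2, n_zero_variance=1, seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
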