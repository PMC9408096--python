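import numpy as np
import pandas as pd
import pytest

import synloc.features as feat
import synloc.simulate as sim
from synloc.types import FeatureMatrix, LabeledDataset


@pytest.fixture(scope="session")
def small_cfg():
    """Small but non-trivial simulation: 2x2 grid, 20 expression features."""
    return sim.SimulationConfig(
        n_positive=60, n_negative=60, n_tissues=2, n_age_stages=2,
        samples_per_cell=5, signal_features=8, effect_size=2.0,
        utr_length_range=(60, 200), seed=7)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return sim.simulate_all(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    """Expression-feature labeled dataset from the small simulation."""
    fm = feat.expression_feature_matrix(
        list(small_sim.labels.index), small_sim.expression)
    return LabeledDataset(fm, small_sim.labels)


def make_planted_dataset(n_per_class=50, n_features=20, n_signal=5,
                         shift=2.0, seed=0):
    """Direct Gaussian planted-signal dataset (no expression layer)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(0.0, 1.0, size=(n, n_features))
    X[:n_per_class, :n_signal] += shift
    ids = [f"g{i:04d}" for i in range(n)]
    names = [f"f{j:03d}" for j in range(n_features)]
    values = pd.DataFrame(X, index=ids, columns=names)
    kinds = pd.Series("expression", index=names)
    labels = pd.Series([1] * n_per_class + [0] * n_per_class, index=ids)
    return LabeledDataset(FeatureMatrix(values, kinds), labels)


@pytest.fixture(scope="session")
def planted_dataset():
    return make_planted_dataset()
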