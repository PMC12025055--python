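import numpy as np
import pytest

from hurstwave.io_formats import FeatureTable, SegmentSet
from hurstwave.preprocess import preprocess_set
from hurstwave.synthetic import SyntheticSpec, gen_dataset


def make_gaussian_table(
    n_per_class: int = 100,
    n_features: int = 10,
    n_informative: int = 4,
    shift: float = 2.0,
    seed: int = 0,
) -> FeatureTable:
    """Cheap two-class Gaussian table: the first ``n_informative`` features
    are mean-shifted by ``shift`` SDs in class 1, the rest are pure noise."""
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n_per_class, n_features))
    X1 = rng.standard_normal((n_per_class, n_features))
    X1[:, :n_informative] += shift
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    names = [f"f{i}" for i in range(n_features)]
    ids = [f"row{i}" for i in range(2 * n_per_class)]
    return FeatureTable(names, X, y, ids)


@pytest.fixture(scope="session")
def gaussian_table() -> FeatureTable:
    return make_gaussian_table()


@pytest.fixture(scope="session")
def small_segset() -> SegmentSet:
    """Six segments per class, generator defaults, preprocessed."""
    clean, rejected = preprocess_set(gen_dataset(6, SyntheticSpec(seed=7)))
    assert not rejected
    return clean
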