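import numpy as np
import pytest

from nirsweep import (
    FeatureDataset,
    SyntheticSpec,
    generate_feature_study,
    kfold_partition,
)


@pytest.fixture(scope="session")
def planted_small():
    """Tiny planted study: 6 channels, channel 2 carries a +2 SD group
    shift and channel 5 a -2 SD shift; 15 trials per group."""
    spec = SyntheticSpec(
        n_trials_per_group=15, n_channels=6, informative={2: 2.0, 5: -2.0}
    )
    ds, truth = generate_feature_study(spec, seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def planted_small_folds(planted_small):
    ds, _ = planted_small
    return kfold_partition(ds.n, 5, ds.t, seed=11)


@pytest.fixture
def separable_2d():
    """Two well-separated 2-D clouds (linearly separable)."""
    rng = np.random.default_rng(7)
    a = rng.normal([2.5, 2.5], 0.5, size=(10, 2))
    b = rng.normal([-2.5, -2.5], 0.5, size=(10, 2))
    X = np.vstack([a, b])
    t = np.array([1] * 10 + [-1] * 10)
    return X, t


def make_dataset(X, t, ids=None):
    ids = ids or tuple(range(1, np.atleast_2d(X).shape[1] + 1))
    return FeatureDataset(X, t, ids)
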