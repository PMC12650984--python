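import numpy as np
import pytest

from brixnet.preprocess import FruitPatchDataset, ReflectanceCube
from brixnet.synthetic_data import SyntheticSceneParams, generate_cube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """Small noiseless scene: exact masks, fast generation."""
    return SyntheticSceneParams(
        n_rows=32, n_cols=32, n_bands=16, noise_sd=0.0, illumination_cv=0.0, seed=0
    )


@pytest.fixture(scope="session")
def noisy_params():
    return SyntheticSceneParams(n_rows=32, n_cols=32, n_bands=16, seed=0)


@pytest.fixture(scope="session")
def small_cube(small_params):
    return generate_cube(small_params, ssc=12.0, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Fruit dataset whose label equals 20x the constant cube reflectance.

    Used to test fold logic and aggregation against oracle predictors: a
    predictor reading any patch value recovers the label exactly.
    """
    wavelengths = np.linspace(400, 1000, 8)
    ids, cubes, masks, labels = [], [], [], []
    rng = np.random.default_rng(0)
    for i in range(12):
        ssc = float(rng.uniform(8, 16))
        data = np.full((12, 12, 8), ssc / 20.0)
        ids.append(f"f{i:02d}")
        cubes.append(ReflectanceCube(data, wavelengths))
        masks.append(np.ones((12, 12), dtype=bool))
        labels.append(ssc)
    return FruitPatchDataset(ids, cubes, masks, np.array(labels), k_centers=3)


def nudge_biases(model_or_params, rng, scale=0.05):
    """Move zero-initialised biases off ReLU kinks before finite differencing."""
    params = model_or_params if isinstance(model_or_params, list) else model_or_params.params()
    for p in params:
        if p.value.ndim <= 1:
            p.value += rng.normal(0, scale, p.value.shape)
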