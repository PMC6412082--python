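import numpy as np
import pytest

from brainpad import AtrophyModel, FeatureVector


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_atrophy():
    """A desk-scale atrophy model for fast map generation in unit tests."""
    return AtrophyModel(grid_shape=(8, 9, 8), voxel_mm=(8.0, 8.0, 8.0),
                        noise_sd=0.05, smoothing_fwhm_mm=4.0)


@pytest.fixture
def make_features(rng):
    """Factory for random feature-vector lists sharing one mask id."""

    def _make(n, d, mask_id="testmask", generator=None):
        g = generator or rng
        X = g.normal(size=(n, d))
        return [FeatureVector(values=x, mask_id=mask_id, subject_id=f"s{i:03d}")
                for i, x in enumerate(X)]

    return _make
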