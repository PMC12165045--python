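import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture(scope="session")
def small_scene_splits():
    """A small synthetic dataset shared by pipeline-level tests."""
    from contourlw import synthetic_fixtures as sf

    return sf.make_dataset(n_scenes=24, seed=7, split_fractions=(0.75, 0.0, 0.25))
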