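import numpy as np
import pytest

from ramantrap import instrument as vi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def physics():
    return vi.TrapPhysics()


@pytest.fixture
def noiseless_config():
    return vi.StreamConfig(seed=7, shot_noise=False, read_noise_sigma=0.0)


@pytest.fixture
def library():
    return vi.default_library()


@pytest.fixture
def ps_particle():
    return vi.ParticleSpec(200.0, {"polystyrene": 1.0}, identity=1)
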