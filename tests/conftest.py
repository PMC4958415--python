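import numpy as np
import pytest

from ctrsa import PhantomConfig, build_study
from ctrsa.phantom import PhantomConfig as _PC


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig(seed=7)


@pytest.fixture(scope="session")
def manifest(default_config):
    return build_study(default_config)


@pytest.fixture(scope="session")
def noiseless_config() -> PhantomConfig:
    return PhantomConfig(seed=7, noise_sd=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def single_bead_config(**overrides) -> PhantomConfig:
    """A small-FOV phantom config for single/few-bead rendering tests."""
    defaults = dict(seed=5, fov_margin=6.0)
    defaults.update(overrides)
    return _PC(**defaults)
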