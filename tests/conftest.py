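import numpy as np
import pytest

from mclegz.phantom import PhantomSpec, default_tis, make_phantom, simulate_mcle


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """(LabelVolume, ground-truth ParameterMaps) for the default phantom."""
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def noiseless_series(phantom):
    _, maps = phantom
    return simulate_mcle(maps, default_tis(), noise_sd=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
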