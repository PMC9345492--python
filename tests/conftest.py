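import numpy as np
import pytest

import astroud as au


@pytest.fixture(scope="session")
def rate_params():
    return au.RateParams()


@pytest.fixture(scope="session")
def spiking_params():
    return au.SpikingParams()


@pytest.fixture(scope="session")
def spiking_run_astro(spiking_params):
    """One reference 15 s spiking run with astrocytes, shared across tests."""
    raster, traces = au.simulate_spiking(spiking_params, duration=15_000.0, seed=1234)
    return raster, traces


@pytest.fixture(scope="session")
def small_spiking_params(spiking_params):
    """Scaled-down network for fast structural tests."""
    return spiking_params.replace(N_E=400, N_I=100, N_A=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
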