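import numpy as np
import pytest

from burstplex import (DRIVER, MODULATOR, EncoderParams, sample_ou,
                       simulate_population)


@pytest.fixture(scope="session")
def short_inputs():
    """20 s driver/modulator pair at the 0.1 ms simulation grid."""
    ss = np.random.SeedSequence(1234)
    d, m = ss.spawn(2)
    drv = sample_ou(DRIVER, 0.1, 20_000.0, d)
    mod = sample_ou(MODULATOR, 0.1, 20_000.0, m)
    return drv, mod


@pytest.fixture(scope="session")
def small_raster(short_inputs):
    """20-neuron, 20 s BSRM raster at the canonical operating point."""
    drv, mod = short_inputs
    params = EncoderParams(tau_rel=6.0, theta_e=-0.10, n_pop=20)
    return simulate_population(params, drv, mod, np.random.SeedSequence(99))
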