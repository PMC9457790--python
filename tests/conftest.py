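import numpy as np
import pytest

from nrfopart.kinetics import NoiseModel, default_params, make_paired_setups, simulate


@pytest.fixture(scope="session")
def noise_free():
    """Degenerate noise model: one replicate, zero scatter."""
    return NoiseModel(sigma_rel=0.0, sigma_abs={}, n_replicates=1, seed=1)


@pytest.fixture(scope="session")
def default_trajectory():
    """Noise-free default-preset trajectory on a dense hourly grid."""
    return simulate(default_params(), np.linspace(0.0, 240.0, 241))


@pytest.fixture(scope="session")
def noise_free_pair(noise_free):
    """Paired with-Fe / without-Fe setups, default preset, no noise."""
    return make_paired_setups(default_params(), noise_free)
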