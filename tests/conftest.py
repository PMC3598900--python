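import numpy as np
import pytest

from subunitscope import (
    NeuronSpec,
    StimulusMovie,
    embed_stimulus,
    make_gabor_strf,
)
from subunitscope.neurons import simulate


@pytest.fixture(scope="session")
def small_design():
    """12-bar Gaussian white-noise design, 8 lags, 30k frames."""
    rng = np.random.default_rng(100)
    movie = StimulusMovie(rng.standard_normal((12, 30_000)), 100.0, "custom")
    return embed_stimulus(movie, 8)


@pytest.fixture(scope="session")
def small_gabor():
    return make_gabor_strf(12, 8, spatial_freq=2.5, tilt_phase_per_lag=0.4,
                           sigma_x=2.0, sigma_t=2.0)


@pytest.fixture(scope="session")
def quadrature_pair_small():
    k1 = make_gabor_strf(12, 8, 2.5, 0.4, 2.0, 2.0, phase=0.0)
    k2 = make_gabor_strf(12, 8, 2.5, 0.4, 2.0, 2.0, phase=np.pi / 2)
    return k1, k2


@pytest.fixture(scope="session")
def energy_cell_data(small_design, quadrature_pair_small):
    """Simulated energy-model complex cell on the small design."""
    k1, k2 = quadrature_pair_small
    spec = NeuronSpec(kind="energy_complex", filters=[k1, k2],
                      spiking_gain=0.5, spiking_offset=-2.0, seed=0)
    rate, spikes = simulate(spec, small_design, seed=200)
    return spec, rate, spikes


@pytest.fixture(scope="session")
def ln_cell_data(small_design, small_gabor):
    spec = NeuronSpec(kind="ln_simple", filters=[small_gabor],
                      spiking_gain=2.0, spiking_offset=-2.0, seed=0)
    rate, spikes = simulate(spec, small_design, seed=201)
    return spec, rate, spikes
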