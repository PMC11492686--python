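import numpy as np
import pytest

from mitorecomb.read_sim import (
    SimulationConfig,
    make_toy_genome,
    mixture_weights,
    simulate_reads,
    toy_isoforms,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_model():
    """Canonical toy: 4 x 9 kb contigs around one 2 kb two-copy repeat."""
    config = SimulationConfig(seed=11, error_rates=(0.0, 0.0, 0.0))
    model, truth = make_toy_genome(config)
    return config, model, truth


@pytest.fixture(scope="session")
def toy_reads():
    """Zero-error reads from a 30% crossover mixture on the canonical toy."""
    config = SimulationConfig(
        seed=5,
        mixture=[0.3],
        read_count=800,
        read_length_mean=6000,
        read_length_sd=2000,
        read_length_min=2500,
        error_rates=(0.0, 0.0, 0.0),
    )
    model, truth = make_toy_genome(config)
    isoforms = toy_isoforms(model, truth)
    weights = mixture_weights(isoforms, 0.3)
    reads, truth = simulate_reads(isoforms, weights, config, model)
    return config, model, isoforms, reads, truth
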