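import numpy as np
import pytest

from modratio import pbn


@pytest.fixture(scope="session")
def default_spec():
    return pbn.default_spec()


@pytest.fixture(scope="session")
def population_counts(default_spec):
    """Exact count moments of the five-population network (session cache)."""
    return pbn.exact_count_moments(default_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_recording(spec, n_bins, rng, cfg=None):
    """One centered spike-count recording from a binary network."""
    states = pbn.sample_states(spec, n_bins, rng)
    return pbn.spike_count_samples(states, cfg, rng)
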