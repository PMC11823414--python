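import numpy as np
import pytest

from lvcspin import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_param():
    """4-state doublet system, 3 sites — fast everywhere."""
    return syn.generate_parametrization(n_states=4, spin_S=0.5, n_sites=3, seed=7)


@pytest.fixture
def sextet_param():
    """12-state sextet system, 8 sites — lanthanide-like but affordable."""
    return syn.generate_parametrization(n_states=12, spin_S=2.5, n_sites=8, seed=11)


@pytest.fixture
def truth_model(small_param):
    return syn.make_ground_truth(small_param, seed=8)


def random_hermitian(rng, n, scale=1.0):
    a = rng.normal(scale=scale, size=(n, n)) + 1j * rng.normal(scale=scale, size=(n, n))
    return 0.5 * (a + a.conj().T)
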