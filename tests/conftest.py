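import numpy as np
import pytest

import ideovine as iv
from ideovine.synth import gen_drydown_dataset


@pytest.fixture(scope="session")
def table():
    return iv.io.load_genotype_table()


@pytest.fixture(scope="session")
def grenache(table):
    return iv.io.genotype("Grenache", table)


@pytest.fixture(scope="session")
def syrah(table):
    return iv.io.genotype("Syrah", table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def drydown_noise_free(grenache):
    """One noise-free mini-lysimeter dry-down of the reference genotype
    (shared across round-trip tests; the generation is the expensive part)."""
    return gen_drydown_dataset(grenache, days=30, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def drydown_gc_fit(grenache, drydown_noise_free):
    """Stomatal-closure sigmoid refit from the shared dry-down."""
    from ideovine.traits import fit_gc_response, gc_psi_pairs, transpiration_and_conductance

    series = drydown_noise_free.series
    balance = transpiration_and_conductance(series, grenache.leaf_area)
    gc, psi = gc_psi_pairs(series, balance)
    return fit_gc_response(gc, psi)
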