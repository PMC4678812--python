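import numpy as np
import pytest

from sirspread import simdata
from sirspread.duplex import load_params


@pytest.fixture(scope="session")
def nn_params():
    return load_params()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared across tests."""
    config = simdata.SimConfig(seed=7, n_chromosomes=2, chromosome_length=30_000,
                               n_genes=20, n_target_genes=6,
                               background_mean=15.0, fold_change=16.0)
    reference, truth, mirnas = simdata.simulate_reference(config)
    reads, library_sizes = simdata.simulate_reads(reference, truth, config)
    return dict(config=config, reference=reference, truth=truth,
                mirnas=mirnas, reads=reads, library_sizes=library_sizes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
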