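import numpy as np
import pytest

from ivtlab.membrane import derive_phenotype, get_tables, pace_single_cell


@pytest.fixture(scope="session")
def warm_kernels():
    """Compile the numba kernels once and return the rate tables."""
    tabs, k1tab = get_tables()
    pace_single_cell(derive_phenotype("epi"), 800.0, 1)
    return tabs, k1tab


@pytest.fixture(scope="session")
def healthy_epi_trace(warm_kernels):
    """A near-steady-state healthy epicardial AP at BCL 800 ms."""
    return pace_single_cell(derive_phenotype("epi"), 800.0, 10)


@pytest.fixture(scope="session")
def remodeled_epi_trace(warm_kernels):
    return pace_single_cell(derive_phenotype("epi", remodeled=True), 800.0, 10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
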