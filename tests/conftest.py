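import numpy as np
import pytest

from riskloci import simulate


@pytest.fixture(scope="session")
def small_panel():
    """500-sample, 50-SNP AR(1) panel with strong LD (rho = 0.9)."""
    return simulate.simulate_ld_panel(500, 50, rho=0.9, seed=101)


@pytest.fixture(scope="session")
def loose_panel():
    """200-sample, 30-SNP panel with moderate LD (rho = 0.5)."""
    return simulate.simulate_ld_panel(200, 30, rho=0.5, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
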