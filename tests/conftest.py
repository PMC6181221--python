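import numpy as np
import pytest

from wgdkit import simgenome as sg


@pytest.fixture(scope="session")
def ancestor():
    """Small ancestral genome shared by read-only tests."""
    g = sg.simulate_ancestral_genome(2, 30, 300, 400, seed=101)
    g.validate()
    return g


@pytest.fixture(scope="session")
def tetraploid_with_truth():
    """Tetraploid at Ks 0.05, full retention (read-only)."""
    g = sg.simulate_ancestral_genome(2, 30, 300, 400, seed=202)
    return sg.apply_wgd(g, target_ks=0.05, ka_ks_ratio=0.3, retention=1.0, seed=203)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
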