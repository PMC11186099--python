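import numpy as np
import pytest

from acnmf.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """Small planted dataset: 4 groups + activity, fast enough for unit tests."""
    cfg = SimConfig(
        n_cells=600, n_genes=800, n_groups=4, act_n_genes=80,
        lib_loc=8.0, seed=3,
    )
    return simulate_counts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
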