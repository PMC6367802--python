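import numpy as np
import pytest

from cypmine import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A compact synthetic study: fast but covers every generator branch."""
    return SimulationConfig(seed=7, n_genes=40, n_true_family=24,
                            motif_catalog_size=30)
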