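import numpy as np
import pytest

from mosaicmap import SimConfig, simulate_pileup


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def control_sites():
    """Ten variant-free ultra-deep control sites (error rate 1e-3)."""
    return simulate_pileup(
        SimConfig(true_maf=0.0, depth=12_000, input_copies=10**9,
                  error_rate=1e-3, seed=11, n_sites=10)
    )
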