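import numpy as np
import pytest

from g4coop.synthetic_data import SimulationConfig, gen_oligo_library


@pytest.fixture(scope="session")
def small_library():
    """A 6-region, 4-barcode library (3 rG4 / 3 non-rG4 regions)."""
    cfg = SimulationConfig(seed=11, n_regions=6, rg4_fraction=0.5,
                           background_rate=1.0, stall_intensity=60.0,
                           five_prime_intensity=30.0)
    seqs, manifest = gen_oligo_library(cfg)
    return cfg, seqs, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
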