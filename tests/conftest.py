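import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-side oracles

from fmtquant import SimConfig, generate_translocation_field


@pytest.fixture(scope="session")
def noise_free_field():
    """A noise-free translocation field with exactly known enrichment 1.5."""
    cfg = SimConfig(
        n_nuclei=4, seed=7, noise_sd=0.0, background_level=0.0,
        marker_amplitude=100.0, target_amplitude=150.0, nuclear_fraction=1.0,
    )
    return generate_translocation_field(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
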