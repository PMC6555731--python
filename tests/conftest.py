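import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from sarcoquant.synthetic import StriationSimConfig, simulate_striation_profile


@pytest.fixture(scope="session")
def cosine_profile_24():
    """Noiseless 2.4 um cosine at 0.1 um/px, 512 samples."""
    return simulate_striation_profile(
        StriationSimConfig(period_um=2.4, pixel_size_um=0.1, n_samples=512,
                           amplitude=100.0, noise_sd=0.0, baseline=200.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
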