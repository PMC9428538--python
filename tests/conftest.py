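import numpy as np
import pytest

from whalesong import CultureConfig, simulate_culture


@pytest.fixture(scope="session")
def clean_culture():
    """Noise-free two-population culture with a revolution in the final year."""
    cfg = CultureConfig(seed=11, noise=0.0, unit_edit_rate=0.0, hybrid_probability=0.0)
    return simulate_culture(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
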