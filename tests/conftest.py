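import numpy as np
import pytest

from wormbench import EngineConfig, default_registry


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def mendelian():
    """Engine with spontaneous males off: the exact-oracle conditions."""
    return EngineConfig(male_rate=0.0)
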