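import numpy as np
import pytest

from safy.forcing import ClimateForcing
from safy.synth import generate_climate


@pytest.fixture(scope="session")
def forcing():
    """One 270-day synthetic season, shared across tests."""
    return generate_climate(seed=42)


@pytest.fixture(scope="session")
def smooth_forcing():
    """Noise-free seasonal sinusoids (for shape/unimodality checks)."""
    d = np.arange(1, 271)
    ta = 18.0 - 10.0 * np.cos(2 * np.pi * (d - 75) / 365.0)
    rg = 18.0 - 10.0 * np.cos(2 * np.pi * (d - 51) / 365.0)
    return ClimateForcing(rg=rg, ta=ta)
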