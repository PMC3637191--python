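import numpy as np
import pytest

from cnvscale import ReadCoverage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noisy_step(rng):
    """Poisson-noise coverage with one planted elevated block."""
    lam = np.full(6000, 3.0)
    lam[2000:3200] = 6.0
    return ReadCoverage("test", rng.poisson(lam))
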