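import numpy as np
import pytest

from metamoran import preset_kernels, two_trait_kernels


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def neutral_kernels():
    return preset_kernels("neutral", N=5, theta0=1.0, lam0=1.0)


@pytest.fixture
def selective_two_trait():
    # trait 1.0 invades trait 0.0 at twice the reverse rate
    return two_trait_kernels(N=5, c_ab=2.0, c_ba=1.0, theta0=1.0, lam0=0.4)
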