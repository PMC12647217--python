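import numpy as np
import pytest

from dgqfs import benchmark_default


@pytest.fixture(scope="session")
def benchmark():
    """The canonical planted-structure benchmark (n=1200, d=128)."""
    return benchmark_default()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
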