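import numpy as np
import pytest

from dcecad.phantom import PhantomConfig, generate_benchmark, generate_phantom_series


@pytest.fixture(scope="session")
def benchmark20():
    """Default 20-slice phantom benchmark (fixed master seed)."""
    return generate_benchmark(20, seed=0)


@pytest.fixture(scope="session")
def single_phantom():
    """One default phantom slice with ground truth."""
    return generate_phantom_series(PhantomConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
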