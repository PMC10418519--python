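import numpy as np
import pytest

from vpaseg.phantom import PhantomSpec, make_template


@pytest.fixture(scope="session")
def template24():
    """Small brain-like template pair shared across fast tests."""
    return make_template(PhantomSpec(dims=24, seed=0))


@pytest.fixture(scope="session")
def template32():
    return make_template(PhantomSpec(dims=32, seed=0))


@pytest.fixture()
def rng_np():
    return np.random.default_rng(1234)
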