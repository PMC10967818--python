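import numpy as np
import pytest

from opdcyto.phantom import PhantomSpec, make_cell_phantom


@pytest.fixture(scope="session")
def h_truth():
    """A rendered H-class phantom (round dim nucleus, vesicles)."""
    return make_cell_phantom(PhantomSpec.for_class("H", rng_seed=11))


@pytest.fixture(scope="session")
def l_truth():
    """A rendered L-class phantom (lobed bright nucleus, no vesicles)."""
    return make_cell_phantom(PhantomSpec.for_class("L", rng_seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
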