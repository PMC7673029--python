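import numpy as np
import pytest

from olspatial import SimConfig, default_barcode_book, gen_tissue


@pytest.fixture(scope="session")
def book():
    return default_barcode_book()


@pytest.fixture(scope="session")
def small_tissue():
    """50 well-separated nuclei over the default two-strip WM/GM field."""
    return gen_tissue(SimConfig(n_nuclei=50, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
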