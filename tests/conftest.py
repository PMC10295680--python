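import numpy as np
import pytest

from crocin_radiolysis import synthetic_data as syn


@pytest.fixture(scope="session")
def crocin_spectrum():
    """Default crocin-like absorptivity fixture (441 nm band at 1.35e5)."""
    return syn.gen_crocin_like_spectrum()


@pytest.fixture(scope="session")
def product_spectrum():
    """Twice-oxidized-product fixture (330/441 nm bands, 375 nm isosbestic)."""
    return syn.gen_product_like_spectrum()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
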