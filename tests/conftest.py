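import numpy as np
import pytest

from fuzzyhybrid.membership import TermParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    """The worked-example constants (b, c, d) = (2, 5, 8)."""
    return TermParams(2.0, 5.0, 8.0)
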