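import numpy as np
import pytest

from reservetarget import StockParams
from reservetarget._engine import StockArrays


@pytest.fixture
def ref_stock():
    """A mid-range life history: 30% annual mortality, moderate growth,
    typical steepness."""
    return StockParams(s=0.7, p=0.7, h=0.7)


@pytest.fixture
def ref_arrays(ref_stock):
    return StockArrays.from_stocks([ref_stock])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
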