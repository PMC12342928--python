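import numpy as np
import pytest

from oceanch4.omp import EndmemberSet
from oceanch4 import synthetic as syn


@pytest.fixture
def two_endmembers():
    ems, ch4 = syn.default_endmembers(2)
    return ems, ch4


@pytest.fixture
def three_endmembers():
    ems, ch4 = syn.default_endmembers(3)
    return ems, ch4


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mix_sample(ems: EndmemberSet, fractions) -> dict:
    """Exact linear mixture of endmember properties."""
    x = np.asarray(fractions, dtype=float)
    props = x @ ems.properties
    from oceanch4.omp import PROPERTIES

    return {p: props[i] for i, p in enumerate(PROPERTIES)}
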