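import numpy as np
import pytest

from quantmct import GroupedSample
from quantmct.contrasts import QuantileSpec


@pytest.fixture
def median_spec():
    return QuantileSpec((0.5,))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_grouped_sample(rng, k=None, sizes=None, dist="normal"):
    """A small random data set for property-style checks."""
    if sizes is None:
        k = k or int(rng.integers(3, 6))
        sizes = rng.integers(12, 30, size=k)
    draws = {
        "normal": lambda n: rng.standard_normal(n),
        "lognormal": lambda n: rng.lognormal(0.0, 1.0, n),
        "t3": lambda n: rng.standard_t(3, n),
    }[dist]
    return GroupedSample([draws(int(n)) for n in sizes])
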