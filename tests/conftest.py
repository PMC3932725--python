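import logging

import numpy as np
import pytest

from metricmine import Image, make_candidate_set, make_phantom

# clamp warnings (expected for the Woods metric) would otherwise flood output
logging.getLogger("metricmine.metrics").setLevel(logging.ERROR)
logging.getLogger("metricmine.mining").setLevel(logging.ERROR)


def img(values, shape=None):
    """Build an Image from a flat list (column grid unless a shape is given)."""
    arr = np.asarray(values, dtype=np.float64)
    if shape is None:
        shape = (arr.size, 1)
    return Image(arr.reshape(shape))


@pytest.fixture(scope="session")
def phantom():
    return make_phantom((16, 16, 8), seed=7)


@pytest.fixture(scope="session")
def small_candidate_set(phantom):
    return make_candidate_set(phantom, n=8, severity_grid=[0.0, 0.2, 0.5, 1.0], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
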