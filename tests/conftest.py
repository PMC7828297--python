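import numpy as np
import pytest

from standtrack.geometry import Box


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, lo=0.0, hi=200.0, min_size=1.0, max_size=60.0) -> Box:
    x1 = rng.uniform(lo, hi)
    y1 = rng.uniform(lo, hi)
    w = rng.uniform(min_size, max_size)
    h = rng.uniform(min_size, max_size)
    return Box(x1, y1, x1 + w, y1 + h)
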