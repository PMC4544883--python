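import math

import numpy as np
import pytest

from trichron import RISeries, SizeClass


@pytest.fixture
def grid_cosine():
    """Unit-amplitude cosine at an exact Fourier grid frequency (k=8, n=64),
    riding on a positive mean so it is a valid width series."""
    n, k = 64, 8
    freq = 2 * math.pi * k / n
    widths = 0.2 + 0.05 * np.cos(freq * np.arange(n))
    return RISeries("grid", SizeClass.SHORT_MEDIUM, widths), freq


def make_series(widths, hair_id="h", size_class=SizeClass.SHORT_MEDIUM):
    return RISeries(hair_id, size_class, np.asarray(widths, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
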