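import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from restiba.core import BoldSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_series(data, tr=3.0, mask=None, **flags):
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, None, None, :]
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(data, tr, mask, **flags)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def small_noise_volume(rng):
    """Seeded 6x6x6x40 volume with a full mask (oracle-equivalence fixture)."""
    vol = rng.normal(0.0, 1.0, size=(6, 6, 6, 40))
    mask = np.ones((6, 6, 6), dtype=bool)
    return vol, mask
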