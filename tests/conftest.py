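import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/reference.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_video(rng):
    """Seeded random integer volume, 12 x 12 x 9 — oracle-comparison scale."""
    return rng.integers(0, 256, size=(12, 12, 9)).astype(float)


@pytest.fixture
def random_image(rng):
    return rng.integers(0, 256, size=(12, 12)).astype(float)
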