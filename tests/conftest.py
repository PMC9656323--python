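import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_gray(seed: int, shape=(16, 16)) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 256, shape).astype(np.uint8)


def random_mask(seed: int, shape=(16, 16), p: float = 0.4) -> np.ndarray:
    return np.random.default_rng(seed).random(shape) < p
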