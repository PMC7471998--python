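import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracles

from melcbp.preprocessing import FrameSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence(rng):
    """A seeded random byte-valued clip, big enough for all descriptors."""
    return FrameSequence(rng.integers(0, 256, size=(10, 16, 16)).astype(float))


@pytest.fixture
def constant_sequence():
    return FrameSequence(np.full((6, 12, 12), 100.0))


def tiny_cube_sequence(values):
    """A 3-frame 3x3 clip from a (3, 3, 3) array — exactly one cube."""
    return FrameSequence(np.asarray(values, dtype=float))
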