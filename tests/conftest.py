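import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_stack():
    """Small deterministic stack: every pixel rises linearly 40 -> 240
    over 21 frames at 10 fps."""
    from dissolvekit.colorimetry import FrameStack

    T, H, W = 21, 4, 4
    vals = np.linspace(40, 240, T)
    frames = np.broadcast_to(vals[:, None, None], (T, H, W)).copy()
    return FrameStack(frames=frames, fps=10.0)


@pytest.fixture
def random_uint8_stack(rng):
    from dissolvekit.colorimetry import FrameStack

    frames = rng.integers(0, 256, size=(30, 8, 8), dtype=np.uint8)
    return FrameStack(frames=frames, fps=60.0)
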