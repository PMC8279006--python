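import numpy as np
import pytest

from glottipress.geometry import ROI, AttachmentLine, FrameSequence
from glottipress.simulate import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless phantom: 200 Hz, 8 kfps, 3 px peak overlap, 4.5 cycles."""
    cfg = PhantomConfig(
        fs=8000.0, f0=200.0, n_frames=180, size=(200, 200),
        amplitude=10.0, overlap_max=3.0, noise_sd=0.0, seed=0,
    )
    seq, gt = generate_phantom(cfg)
    return cfg, seq, gt


@pytest.fixture
def midline_lines():
    left = AttachmentLine((99.5, 30), (99.5, 170), side="left")
    right = AttachmentLine((99.5, 30), (99.5, 170), side="right")
    return left, right


@pytest.fixture
def full_roi():
    return ROI(0, 0, 200, 200)


@pytest.fixture
def static_sequence():
    frame = np.full((40, 40), 0.5)
    frame[10:30, 18:22] = 0.1
    return FrameSequence(np.repeat(frame[None], 12, axis=0), fs=4000.0)
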