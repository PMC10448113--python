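import numpy as np
import pytest

from glomod.protocol import make_protocol
from glomod.synthetic import generate_roi_dataset


@pytest.fixture(scope="session")
def protocol():
    """Small deterministic protocol: one pair of sequences, 1 Hz."""
    return make_protocol(repeats=2, frame_rate=1.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(protocol):
    """60 synthetic ROIs at SNR 10 with ground truth."""
    return generate_roi_dataset(60, protocol, snr=10.0, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
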