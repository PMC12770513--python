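import numpy as np
import pytest

from noctomap.io_sync import Segment, TriaxialRecording


def make_recording(ax, ay, az, fs=100.0, t0=0.0, segment=Segment.LW):
    return TriaxialRecording(segment, fs, t0,
                             np.asarray(ax, float), np.asarray(ay, float),
                             np.asarray(az, float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_recording(rng):
    """30 s of rest: gravity on z plus 2 mg sensor noise."""
    n = 3000
    return make_recording(rng.normal(0, 0.002, n),
                          rng.normal(0, 0.002, n),
                          1.0 + rng.normal(0, 0.002, n))
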