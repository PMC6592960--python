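import numpy as np
import pytest

from dirconn.recording import MultichannelRecording, SegmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_recording(rng):
    """30 s of unit-variance bivariate white noise at 1 kHz."""
    return MultichannelRecording(
        data=rng.standard_normal((30000, 2)),
        fs=1000.0,
        channel_labels=["F", "P"],
        condition="W",
        modality="SYNTH",
    )


def make_segments(data: np.ndarray, fs: float = 1000.0, seg_s: float = 2.0) -> SegmentSet:
    """Split an array into as many whole segments as it holds."""
    seg_len = int(seg_s * fs)
    n = data.shape[0] // seg_len
    return SegmentSet(
        segments=[data[i * seg_len : (i + 1) * seg_len] for i in range(n)],
        fs=fs,
        seg_duration_s=seg_s,
    )
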