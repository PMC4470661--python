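import numpy as np
import pytest

from fetalmotion.detection import SignalEvent
from fetalmotion.io_formats import PipelineConfig, Recording


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def short_recording(rng) -> Recording:
    """60 s of two-channel noise at 100 Hz."""
    n = 6000
    return Recording(
        subject_id="s1",
        gestational_week=32,
        sampling_rate=100.0,
        fm=rng.normal(0, 0.2, n),
        mm=rng.normal(0, 0.2, n),
    )


def make_event(
    start: float,
    end: float,
    channel: str = "FM",
    peak: float = 50.0,
    status: str = "accepted",
    reason: str = "none",
) -> SignalEvent:
    return SignalEvent(
        channel=channel,
        start_s=start,
        end_s=end,
        peak_integral=peak,
        status=status,
        reason=reason,
    )
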