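import numpy as np
import pytest

from tbivitals.synthetic import MorphParams


@pytest.fixture
def morph() -> MorphParams:
    return MorphParams()


@pytest.fixture
def beat_times_10() -> np.ndarray:
    """Ten beats at 800 ms spacing with a 0.5 s lead-in."""
    return 0.5 + np.arange(10) * 0.8


def regular_beats(hr_bpm: float, duration_s: float, lead_in: float = 0.5) -> np.ndarray:
    """Evenly spaced beat times at a given heart rate."""
    period = 60.0 / hr_bpm
    n = int(duration_s / period)
    return lead_in + np.arange(n) * period
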