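from datetime import datetime

import numpy as np
import pytest

from stepsense import RawRecording
from stepsense.simulator import GaitBoutSpec, simulate_bout

START = datetime(2022, 1, 3, 12, 0, 0)


@pytest.fixture
def still_recording() -> RawRecording:
    """60 s of still wear: gravity on z plus jitter far below any variance threshold."""
    rng = np.random.default_rng(11)
    samples = np.tile([0.0, 0.0, 1.0], (6000, 1)) + rng.uniform(-1e-3, 1e-3, (6000, 3))
    return RawRecording(START, 100.0, samples)


@pytest.fixture
def gait_recording():
    """Noise-free 60 s bout at 110 steps/min, 0.7 g swing; returns (recording, step times)."""
    return simulate_bout(GaitBoutSpec(cadence_spm=110, duration_s=60, swing_amplitude_g=0.7))


def random_recording(seed: int, n: int = 1000, rate: float = 100.0) -> RawRecording:
    """Rough wrist-like random signal: gravity baseline plus broadband noise."""
    rng = np.random.default_rng(seed)
    samples = np.array([0.0, 0.0, 1.0]) + rng.normal(0.0, 0.3, (n, 3))
    np.clip(samples, -8.0, 8.0, out=samples)
    return RawRecording(START, rate, samples)
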