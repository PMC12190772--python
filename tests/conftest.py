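import numpy as np
import pytest

from msalpha.core import EEGRecording
from msalpha.synth import GroundTruth, make_templates


def uniform_tp(k: int) -> np.ndarray:
    """Uniform off-diagonal transition matrix."""
    tp = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(tp, 0.0)
    return tp


@pytest.fixture
def five_state_truth() -> GroundTruth:
    """5 states, 32 channels, 90 ms dwells, child-like alpha/aperiodic."""
    return GroundTruth(
        templates=make_templates(5, 32, seed=11),
        tp_matrix=uniform_tp(5),
        mean_durations=np.full(5, 90.0),
        alpha_cf=9.0,
        alpha_peak_power=0.6,
        aperiodic_offset=1.5,
        aperiodic_exponent=1.4,
        seed=11,
    )


@pytest.fixture
def sine_recording() -> EEGRecording:
    """10 s of a 10 Hz sine on 4 channels at 250 Hz, 50 µV amplitude."""
    fs = 250.0
    t = np.arange(int(10 * fs)) / fs
    x = 50.0 * np.sin(2 * np.pi * 10.0 * t)
    data = np.column_stack([x, -x, 0.5 * x, -0.5 * x])
    return EEGRecording(data=data, fs=fs)
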