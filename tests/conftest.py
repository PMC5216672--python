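import numpy as np
import pandas as pd
import pytest

from chorusspace.calibration import AudioClip, CalibrationSpec
from chorusspace.commspace import PropagationParams
from chorusspace.synthetic_data import SyntheticConfig


@pytest.fixture
def calib():
    return CalibrationSpec(mic_sensitivity=-36.0, gain=20.0, adc_full_scale=1.0)


@pytest.fixture
def unity_calib():
    """Sensitivity + gain = 0 dB, full scale 1 V: digital x == x Pa."""
    return CalibrationSpec(mic_sensitivity=-36.0, gain=36.0, adc_full_scale=1.0)


@pytest.fixture
def params():
    return PropagationParams(excess_attenuation=0.2)


@pytest.fixture
def default_config():
    return SyntheticConfig(seed=1)


def tone_clip(freq, duration, amplitude, sample_rate=44100.0, units="pa"):
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    return AudioClip(amplitude * np.sin(2 * np.pi * freq * t), sample_rate, units=units)


@pytest.fixture
def two_frog_table():
    return pd.DataFrame(
        [
            {"frog": "F1", "distance_m": 5.0, "source_level_db": 90.0,
             "centroid_frequency_hz": 2400.0, "duration_s": 0.30, "call_rate_cpm": 12.0},
            {"frog": "F2", "distance_m": 8.0, "source_level_db": 86.0,
             "centroid_frequency_hz": 2600.0, "duration_s": 0.25, "call_rate_cpm": 6.0},
        ]
    )
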