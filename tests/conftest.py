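import numpy as np
import pytest

from wearecg import DetectorConfig, generate_ecg, run_detector


@pytest.fixture(scope="session")
def clean_record():
    """One minute of clean synthetic ECG at 60 BPM, 1 kHz."""
    return generate_ecg(bpm=60, duration=60, fs=1000, seed=7)


@pytest.fixture(scope="session")
def clean_detection(clean_record):
    return run_detector(clean_record.signal)


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
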