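import numpy as np
import pytest

from apneaebr.pipeline import extract_subject_features
from apneaebr.synthetic import SyntheticConfig, generate_recording

FS = 128.0
FRAME_LEN = 1280


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(duration=1200.0, n_events=10, seed=1)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_recording(small_config)


@pytest.fixture(scope="session")
def small_features(small_recording):
    recording, annotations = small_recording
    X, names, labels, starts = extract_subject_features(
        recording, annotations, channels=("C3-A2", "C4-A1"), guard=30.0
    )
    return X, names, labels, starts
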