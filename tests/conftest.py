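import hypothesis
import numpy as np
import pytest

from emgsrd import SimConfig, bandpass_notch, default_profiles, generate_dataset

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """One subject, 2 s holds at 1000 Hz — enough for fast pipeline tests."""
    return SimConfig(n_subjects=1, fs=1000.0, duration_s=2.0, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """Filtered 1-subject dataset: 15 classes x 3 trials of 2 s recordings."""
    return [bandpass_notch(r) for r in generate_dataset(tiny_config)]


@pytest.fixture(scope="session")
def profiles():
    return default_profiles(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
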