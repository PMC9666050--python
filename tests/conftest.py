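import numpy as np
import pytest

from semgkit.signal_io import Recording
from semgkit.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trial_set():
    """One synthetic subject with well-separated classes (6 x 8 trials)."""
    spec = SyntheticSpec(n_subjects=1, n_trials_per_class=8, separation=2.0, seed=11)
    return generate(spec)


@pytest.fixture
def two_channel_recording(rng):
    samples = rng.normal(scale=1e-2, size=(3000, 2))
    return Recording(samples=samples, rate=500.0, label="CY", subject="s1", trial=0)
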