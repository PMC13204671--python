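import numpy as np
import pytest

from semgmap import Recording, easy_spec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """8-channel 0.5 s recording with amplitudes in the physiological range."""
    amps = 10.0 ** rng.uniform(-6, -4, size=(8, 1))
    return Recording(amps * rng.standard_normal((8, 1000)), fs=2000.0,
                     label=0, subject="S1")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Short easy-regime dataset shared by the slower harness tests."""
    spec = easy_spec(seed=7, duration=1.5)
    recs, labels, manifest = generate_dataset(spec, reps_per_class=3)
    return recs, labels, manifest
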