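import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    from cemarker.io import EEGRecording

    data = rng.standard_normal((3, 1500))
    return EEGRecording("sub-01", ("Fz", "Cz", "Pz"), 250.0, data)
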