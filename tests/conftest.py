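import numpy as np
import pytest

from oxiflow.preprocessing import LabeledWindow
from oxiflow.synthetic_data import Activity, CircuitProtocol, SubjectParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_subject():
    """Noise-free subject so closed-form signal properties hold exactly."""
    return SubjectParams(subject_id="quiet", noise_sd_g=0.0, noise_sd_dps=0.0, seed=7)


@pytest.fixture
def short_protocol():
    """A compressed circuit (30 s rest, 120 s circuit, 30 s rest) for fast tests."""
    lap = (
        (Activity.WALKING, 45.0),
        (Activity.UPSTAIRS, 9.0),
        (Activity.WALKING, 39.0),
        (Activity.DOWNSTAIRS, 9.0),
        (Activity.WALKING, 18.0),
    )
    return CircuitProtocol(
        rest_before_s=30.0,
        circuit_s=120.0,
        rest_after_s=30.0,
        segment_plan=lap,
        stop_probability=0.0,
        segments_per_lap=5,
    )


@pytest.fixture
def random_window(rng):
    def make(n=75, scale=1.0, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return LabeledWindow(samples=scale * r.normal(size=(n, 6)), label=0)

    return make
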