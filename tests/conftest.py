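import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from vocogaze.fixation import AOILayout
from vocogaze.ocular import OcularTrace, TrialRecord


@pytest.fixture
def layout():
    return AOILayout()


def make_trace(pupil, rate=250.0, x=None, y=None, valid=None, t0=0.0):
    """Build an OcularTrace from a pupil array with sensible defaults."""
    pupil = np.asarray(pupil, dtype=float)
    n = len(pupil)
    t = t0 + 1000.0 / rate * np.arange(n)
    if x is None:
        x = np.full(n, 512.0)
    if y is None:
        y = np.full(n, 384.0)
    if valid is None:
        valid = pupil > 0
    return OcularTrace(t, x, y, pupil, np.asarray(valid, dtype=bool), rate)


def make_trial(word_onset_ms=2000.0, condition="target_matching",
               clicked="target", correct=True, trial_id=0):
    return TrialRecord(trial_id, condition, "NS", word_onset_ms - 1000.0,
                       word_onset_ms, clicked, correct)


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def trial_factory():
    return make_trial
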