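import numpy as np
import pytest

from gazecog import (
    ROI,
    GazeRecording,
    SegmentKind,
    TaskSegment,
    TaskTimeline,
    build_default_timeline,
)


@pytest.fixture(scope="session")
def default_timeline():
    return build_default_timeline()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(t, x, y, valid, subject_id="s", rate=50.0):
    """Shorthand recording constructor for fixtures."""
    return GazeRecording(
        subject_id,
        np.asarray(t, dtype=float),
        np.asarray(x, dtype=float),
        np.asarray(y, dtype=float),
        np.asarray(valid, dtype=bool),
        nominal_rate_hz=rate,
    )


def single_choice_timeline(duration=10.0, roi=None, task_id="c"):
    """A one-segment scored timeline for isolated scoring tests."""
    roi = roi if roi is not None else ROI(0.5, 0.5, 1.0, 1.0)
    seg = TaskSegment(task_id, 0.0, duration, SegmentKind.CHOICE, roi, scored=True)
    return TaskTimeline([seg])


def random_recording(rng, n=200, subject_id="r"):
    """Random but valid recording: strictly increasing times, coords in
    range for valid samples, poison coords on invalid ones."""
    t = np.cumsum(rng.uniform(0.005, 0.05, n))
    valid = rng.random(n) < 0.8
    x = rng.random(n)
    y = rng.random(n)
    x[~valid] = 99.0
    y[~valid] = -5.0
    return GazeRecording(subject_id, t, x, y, valid)
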