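"""Fixation-duration scoring.

The per-task measure is the percentage of fixation duration on the
target ROI during the task's scored (CHOICE) window.  No saccade or
fixation event detection is performed: a sample either falls inside the
ROI or it does not.  The denominator is the time for which valid gaze
was actually detected — counted in samples, which at the device's fixed
nominal rate is proportional to time and robust to dropped frames —
never the total task duration, so blinks and looking away do not
penalize the score.

The aggregate eye-tracking cognitive score is 100 x the unweighted
arithmetic mean of the per-task fractions over the nine scored tasks.
A task fraction is undefined (QC fail) when fewer than
``min_valid_fraction`` (default 10%) of the window's samples are valid;
the aggregate is QC-failed when fewer than ``min_tasks`` (default 7 of
9) task fractions are defined.  Undefined fractions are never coerced
to zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .gaze_model import GazeRecording
from .task_schema import TaskSegment, TaskTimeline

__all__ = [
    "TaskScore",
    "CognitiveScore",
    "MmseCategory",
    "compute_task_score",
    "compute_cognitive_score",
    "recording_efficiency",
    "mmse_category",
    "DEFAULT_MIN_VALID_FRACTION",
    "DEFAULT_MIN_TASKS",
]

#: A task fraction is defined only if at least this share of the window's
#: samples are valid; prevents a lone surviving sample from becoming a
#: 0% or 100% task score.
DEFAULT_MIN_VALID_FRACTION = 0.10
#: The aggregate passes QC only if at least this many task fractions are
#: defined.
DEFAULT_MIN_TASKS = 7


@dataclass(frozen=True)
class TaskScore:
    """Per-task fixation fraction with its sample counts and QC flag.

    ``fraction`` is ``None`` when undefined (QC fail).
    """

    task_id: str
    n_window: int
    n_valid: int
    n_in_roi: int
    fraction: float | None
    qc_pass: bool

    def __post_init__(self) -> None:
        if not (0 <= self.n_in_roi <= self.n_valid <= self.n_window):
            raise ValidationError(
                f"task {self.task_id}: counts must satisfy "
                f"0 <= n_in_roi <= n_valid <= n_window, got "
                f"({self.n_in_roi}, {self.n_valid}, {self.n_window})"
            )
        if (self.fraction is not None) != self.qc_pass:
            raise ValidationError(
                f"task {self.task_id}: fraction defined iff qc_pass"
            )


@dataclass(frozen=True)
class CognitiveScore:
    """Aggregate eye-tracking cognitive score for one recording.

    ``et_score`` = 100 x unweighted mean of the defined task fractions,
    ``None`` when no task fraction is defined.
    """

    subject_id: str
    task_scores: tuple[TaskScore, ...]
    et_score: float | None
    n_tasks_used: int
    recording_efficiency: float | None
    qc_pass: bool


def _window_mask(recording: GazeRecording, segment: TaskSegment) -> np.ndarray:
    # half-open in time, mirroring the spatial convention
    return (recording.t >= segment.onset) & (recording.t < segment.offset)


def compute_task_score(
    recording: GazeRecording,
    segment: TaskSegment,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> TaskScore:
    """Score one CHOICE window: valid-sample fraction inside the ROI.

    fraction = (valid samples with gaze in target ROI) /
               (valid samples in [onset, offset))
    """
    if not segment.scored or segment.target_roi is None:
        raise ValidationError(f"segment {segment.task_id} is not a scored segment")
    in_win = _window_mask(recording, segment)
    n_window = int(in_win.sum())
    v = in_win & recording.valid
    n_valid = int(v.sum())
    if n_valid > 0:
        inside = segment.target_roi.contains(recording.x[v], recording.y[v])
        n_in_roi = int(np.count_nonzero(inside))
    else:
        n_in_roi = 0
    defined = n_valid > 0 and n_valid >= min_valid_fraction * n_window
    return TaskScore(
        task_id=segment.task_id,
        n_window=n_window,
        n_valid=n_valid,
        n_in_roi=n_in_roi,
        fraction=(n_in_roi / n_valid) if defined else None,
        qc_pass=defined,
    )


def compute_cognitive_score(
    recording: GazeRecording,
    timeline: TaskTimeline,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    min_tasks: int = DEFAULT_MIN_TASKS,
) -> CognitiveScore:
    """Aggregate score over the timeline's scored windows.

    The mean is unweighted across tasks and taken over the defined
    fractions only; ``n_tasks_used`` reports how many contributed.
    """
    scores = tuple(
        compute_task_score(recording, seg, min_valid_fraction)
        for seg in timeline.scored_segments()
    )
    defined = [s.fraction for s in scores if s.fraction is not None]
    n_used = len(defined)
    et = 100.0 * float(np.mean(defined)) if n_used else None
    eff = recording_efficiency(recording, timeline)
    return CognitiveScore(
        subject_id=recording.subject_id,
        task_scores=scores,
        et_score=et,
        n_tasks_used=n_used,
        recording_efficiency=eff,
        qc_pass=n_used >= min_tasks,
    )


def recording_efficiency(
    recording: GazeRecording, timeline: TaskTimeline
) -> float | None:
    """Fraction of samples over the whole task sequence
    [first onset, last offset) for which gaze was detected.

    ``None`` (QC failure) when the recording has no samples in the span.
    """
    start, end = timeline.span
    in_span = (recording.t >= start) & (recording.t < end)
    n = int(in_span.sum())
    if n == 0:
        return None
    return float(np.count_nonzero(recording.valid & in_span)) / n


class MmseCategory(str, enum.Enum):
    """MMSE severity bands: Low 0-20 (severely impaired), Middle 21-26
    (mildly impaired), High 27-30 (no apparent impairment)."""

    LOW = "LOW"
    MIDDLE = "MIDDLE"
    HIGH = "HIGH"


def mmse_category(mmse: int) -> MmseCategory:
    """Map an MMSE total (integer 0-30) to its severity band."""
    if not float(mmse).is_integer() or not (0 <= mmse <= 30):
        raise ValidationError(f"MMSE must be an integer in [0, 30], got {mmse}")
    mmse = int(mmse)
    if mmse <= 20:
        return MmseCategory.LOW
    if mmse <= 26:
        return MmseCategory.MIDDLE
    return MmseCategory.HIGH
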