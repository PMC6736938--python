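"""Task-timeline schema and the default 178-s, ten-task protocol.

The assessment presents ten short task movies and pictures over 178 s.
Each task occupies a contiguous window; tasks with a cue/count phase are
split into a CUE segment followed by the CHOICE segment in which the
correct-answer image is on screen.  Only CHOICE segments are scored,
each against an axis-aligned rectangular target ROI in normalized
coordinates.  Nine tasks are scored (3, 4, 5, 6, 7, 8, 9, 10, 1-b); the
memory-encoding task (1-a) and the smooth-pursuit task (2) are not.

Timing anchors of the default protocol:

* per-task durations 14, 11, 10, 20, 56 (tasks 5-7), 24 (tasks 8-9),
  20 and 10 s — these sum to 165 s;
* the recall task 1-b begins 154 s after the encoding task 1-a ends;
* the whole sequence lasts 178 s.

The remaining 13 s are inter-task TRANSITION segments: 1 s after each
of tasks 2..9 and 5 s after task 10, all before the recall task, which
reconciles all three anchors (14 + 154 = 168 = recall onset,
168 + 10 = 178).

Containment is half-open in both space ([x0, x1) x [y0, y1)) and time
([onset, offset)), so tiled ROIs and adjacent windows never
double-count a sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError

__all__ = [
    "ROI",
    "SegmentKind",
    "TaskSegment",
    "TaskTimeline",
    "build_default_timeline",
    "read_timeline",
    "write_timeline",
    "point_in_roi",
]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle in normalized screen coordinates
    containing the target (correct-answer) image."""

    x0: float
    y0: float
    x1: float
    y1: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.x0 < self.x1 <= 1.0 and 0.0 <= self.y0 < self.y1 <= 1.0):
            raise ConfigError(
                f"ROI must satisfy 0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1, "
                f"got ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def contains(self, x, y):
        """Half-open containment; vectorizes over array inputs."""
        return (
            (np.asarray(x) >= self.x0)
            & (np.asarray(x) < self.x1)
            & (np.asarray(y) >= self.y0)
            & (np.asarray(y) < self.y1)
        )


def point_in_roi(x: float, y: float, roi: ROI) -> bool:
    """True iff (x, y) lies in the half-open rectangle
    [x0, x1) x [y0, y1)."""
    return bool(roi.contains(x, y))


class SegmentKind(str, enum.Enum):
    ENCODING = "ENCODING"
    PURSUIT = "PURSUIT"
    CHOICE = "CHOICE"
    CUE = "CUE"
    TRANSITION = "TRANSITION"


@dataclass(frozen=True)
class TaskSegment:
    """One contiguous window of the protocol.

    ``scored`` implies the segment is a CHOICE window with a target ROI.
    """

    task_id: str
    onset: float
    offset: float
    kind: SegmentKind
    target_roi: ROI | None = None
    scored: bool = False

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ConfigError(
                f"segment {self.task_id}: onset ({self.onset}) must precede "
                f"offset ({self.offset})"
            )
        if self.scored:
            if self.kind is not SegmentKind.CHOICE:
                raise ConfigError(
                    f"segment {self.task_id}: scored segments must be CHOICE, "
                    f"got {self.kind.value}"
                )
            if self.target_roi is None:
                raise ConfigError(
                    f"segment {self.task_id}: scored segment lacks target_roi"
                )

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def shifted(self, dt: float) -> "TaskSegment":
        return TaskSegment(
            self.task_id, self.onset + dt, self.offset + dt, self.kind,
            self.target_roi, self.scored,
        )


class TaskTimeline:
    """Ordered, non-overlapping sequence of task segments."""

    def __init__(self, segments: Sequence[TaskSegment]) -> None:
        segments = sorted(segments, key=lambda s: s.onset)
        for a, b in zip(segments, segments[1:]):
            if b.onset < a.offset:
                raise ConfigError(
                    f"segments {a.task_id} and {b.task_id} overlap "
                    f"([{a.onset}, {a.offset}) vs [{b.onset}, {b.offset}))"
                )
        self.segments: tuple[TaskSegment, ...] = tuple(segments)

    @property
    def total_duration(self) -> float:
        if not self.segments:
            return 0.0
        return self.segments[-1].offset - self.segments[0].onset

    @property
    def span(self) -> tuple[float, float]:
        if not self.segments:
            return (0.0, 0.0)
        return (self.segments[0].onset, self.segments[-1].offset)

    def scored_segments(self) -> list[TaskSegment]:
        return [s for s in self.segments if s.scored]

    def task_ids(self) -> list[str]:
        """Distinct task IDs in presentation order (TRANSITIONs excluded)."""
        seen: list[str] = []
        for s in self.segments:
            if s.kind is SegmentKind.TRANSITION:
                continue
            if s.task_id not in seen:
                seen.append(s.task_id)
        return seen

    @property
    def n_tasks(self) -> int:
        """Number of distinct tasks; the encoding/recall parts of a
        split task (IDs like "1a"/"1b") count as one task."""
        bases = {tid.rstrip("ab") for tid in self.task_ids()}
        return len(bases)

    def segment(self, task_id: str, kind: SegmentKind | None = None) -> TaskSegment:
        for s in self.segments:
            if s.task_id == task_id and (kind is None or s.kind is kind):
                return s
        raise KeyError(f"no segment with task_id={task_id!r}, kind={kind}")

    def shifted(self, dt: float) -> "TaskTimeline":
        return TaskTimeline([s.shifted(dt) for s in self.segments])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaskTimeline) and self.segments == other.segments


# ---------------------------------------------------------------------------
# Default protocol
# ---------------------------------------------------------------------------

# (task_id, task duration s, kind of single-phase task or None for two-phase,
#  choice duration s or None for whole window, target cell in its layout)
# Two-phase tasks (4, 5-7, 8-9, 10) show a cue/count display first; the
# correct answer exists on screen only during the choice display, modeled
# as the second half of the task window by default (config-editable).
# The combined printed durations (tasks 5-7: 56 s, tasks 8-9: 24 s) are
# split 14/18/24 (difficulty, hence length, rises from task 5 to 7) and
# 12/12.  ROIs default to the target image's cell in a plausible layout;
# real deployments recalibrate them from the stimulus geometry.

_GRID_3X2 = [(c / 3, r / 2, (c + 1) / 3, (r + 1) / 2) for r in range(2) for c in range(3)]
_GRID_2X2 = [(c / 2, r / 2, (c + 1) / 2, (r + 1) / 2) for r in range(2) for c in range(2)]
_GRID_4X2 = [(c / 4, r / 2, (c + 1) / 4, (r + 1) / 2) for r in range(2) for c in range(4)]
_GRID_3X1 = [(c / 3, 0.25, (c + 1) / 3, 0.75) for c in range(3)]
_GRID_5X1 = [(c / 5, 0.3, (c + 1) / 5, 0.7) for c in range(5)]


def _roi(cell: tuple[float, float, float, float], label: str) -> ROI:
    return ROI(*cell, label=label)


def build_default_timeline() -> TaskTimeline:
    """Build the default ten-task, 178-s protocol.

    Returns a timeline with nine scored CHOICE windows (tasks 3, 4, 5,
    6, 7, 8, 9, 10, 1-b); task 1-a (encoding) and task 2 (smooth
    pursuit) are unscored.
    """
    segs: list[TaskSegment] = []
    t = 0.0

    def add(seg: TaskSegment) -> None:
        segs.append(seg)

    def transition(dur: float, after: str) -> None:
        nonlocal t
        add(TaskSegment(f"trans-{after}", t, t + dur, SegmentKind.TRANSITION))
        t += dur

    # Task 1-a: memory encoding, 14 s, unscored.
    add(TaskSegment("1a", t, t + 14.0, SegmentKind.ENCODING))
    t += 14.0
    # Task 2: smooth pursuit, 11 s, unscored.
    add(TaskSegment("2", t, t + 11.0, SegmentKind.PURSUIT))
    t += 11.0
    transition(1.0, "2")
    # Task 3: odd-one-out, 10 s, whole window scored (6 objects, 3x2 grid).
    add(
        TaskSegment(
            "3", t, t + 10.0, SegmentKind.CHOICE,
            _roi(_GRID_3X2[4], "odd-one-out target"), scored=True,
        )
    )
    t += 10.0
    transition(1.0, "3")
    # Two-phase tasks: (id, duration, layout cell, label)
    two_phase = [
        ("4", 20.0, _GRID_2X2[2], "pattern-match target"),
        ("5", 14.0, _GRID_4X2[1], "subtraction answer (easy)"),
        ("6", 18.0, _GRID_4X2[6], "subtraction answer (medium)"),
        ("7", 24.0, _GRID_4X2[3], "subtraction answer (hard)"),
        ("8", 12.0, _GRID_5X1[2], "pentagon"),
        ("9", 12.0, _GRID_5X1[3], "hexagon"),
        ("10", 20.0, _GRID_3X1[2], "double pentagon target"),
    ]
    for task_id, dur, cell, label in two_phase:
        half = dur / 2.0
        add(TaskSegment(task_id, t, t + half, SegmentKind.CUE))
        add(
            TaskSegment(
                task_id, t + half, t + dur, SegmentKind.CHOICE,
                _roi(cell, label), scored=True,
            )
        )
        t += dur
        transition(5.0 if task_id == "10" else 1.0, task_id)
    # Task 1-b: memory recall, 10 s, whole window scored (5 foods, 5x1).
    add(
        TaskSegment(
            "1b", t, t + 10.0, SegmentKind.CHOICE,
            _roi(_GRID_5X1[1], "recalled food"), scored=True,
        )
    )
    t += 10.0
    return TaskTimeline(segs)


# ---------------------------------------------------------------------------
# YAML config I/O
# ---------------------------------------------------------------------------


def _segment_to_dict(s: TaskSegment) -> dict:
    d: dict = {
        "task_id": s.task_id,
        "onset": float(s.onset),
        "offset": float(s.offset),
        "kind": s.kind.value,
        "scored": bool(s.scored),
    }
    if s.target_roi is not None:
        d["target_roi"] = {
            "x0": float(s.target_roi.x0),
            "y0": float(s.target_roi.y0),
            "x1": float(s.target_roi.x1),
            "y1": float(s.target_roi.y1),
            "label": s.target_roi.label,
        }
    return d


def _segment_from_dict(d: dict) -> TaskSegment:
    try:
        roi = None
        if d.get("target_roi") is not None:
            r = d["target_roi"]
            roi = ROI(
                float(r["x0"]), float(r["y0"]), float(r["x1"]), float(r["y1"]),
                label=str(r.get("label", "")),
            )
        return TaskSegment(
            task_id=str(d["task_id"]),
            onset=float(d["onset"]),
            offset=float(d["offset"]),
            kind=SegmentKind(str(d["kind"])),
            target_roi=roi,
            scored=bool(d.get("scored", False)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"malformed segment entry {d!r}: {exc}") from exc


def write_timeline(timeline: TaskTimeline, path) -> None:
    """Serialize a timeline to a YAML config file."""
    doc = {"segments": [_segment_to_dict(s) for s in timeline.segments]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_timeline(path) -> TaskTimeline:
    """Parse a YAML timeline config, validating all invariants."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "segments" not in doc:
        raise ConfigError(f"timeline config {path} must be a mapping with 'segments'")
    if not isinstance(doc["segments"], list):
        raise ConfigError(f"timeline config {path}: 'segments' must be a list")
    return TaskTimeline([_segment_from_dict(d) for d in doc["segments"]])
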