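"""Core gaze data types and delimited-text I/O.

A gaze recording is a single stream of timestamped gaze points in
normalized screen coordinates (origin top-left, x and y in [0, 1]),
each flagged valid or invalid by the tracker.  Invalid samples carry no
usable position: every downstream computation ignores their coordinates.
Sampling is nominally 50 Hz but irregular spacing is tolerated — scoring
counts samples rather than wall time, and at a fixed nominal rate the
two are proportional.

Clinical metadata (group label, MMSE, optionally ADAS-Cog / FAB / CDR)
lives in :class:`SubjectRecord` rows collected into a :class:`Cohort`.
Missing clinical scores are first-class: they are preserved as missing,
never imputed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError

__all__ = [
    "Group",
    "GazeSample",
    "ScreenGeometry",
    "GazeRecording",
    "SubjectRecord",
    "Cohort",
    "read_gaze_log",
    "write_gaze_log",
    "read_cohort",
    "write_cohort",
]

#: Valid CDR severity levels.
CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)


class Group(str, enum.Enum):
    """Clinical group label: healthy control, mild cognitive impairment,
    or dementia."""

    HC = "HC"
    MCI = "MCI"
    DEMENTIA = "DEMENTIA"

    @classmethod
    def parse(cls, label: str) -> "Group":
        try:
            return cls(str(label).strip().upper())
        except ValueError:
            raise DataError(f"unknown group label: {label!r}") from None


@dataclass(frozen=True)
class GazeSample:
    """One tracker sample: time (s), normalized position, validity flag.

    When ``valid`` is False the coordinates are meaningless and must be
    ignored downstream.
    """

    t: float
    x: float
    y: float
    valid: bool

    def __post_init__(self) -> None:
        if self.t < 0 or not math.isfinite(self.t):
            raise ValidationError(f"sample time must be finite and >= 0, got {self.t}")
        if self.valid:
            if not (math.isfinite(self.x) and math.isfinite(self.y)):
                raise ValidationError("valid sample has non-finite coordinates")
            if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
                raise ValidationError(
                    f"valid sample coordinates out of [0,1]: ({self.x}, {self.y})"
                )


@dataclass(frozen=True)
class ScreenGeometry:
    """Monitor geometry used to normalize pixel coordinates."""

    width_px: int = 1280
    height_px: int = 1024
    diagonal_inches: float | None = 19.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("screen dimensions must be positive")
        if self.diagonal_inches is not None and self.diagonal_inches <= 0:
            raise ValidationError("diagonal_inches must be positive")


class GazeRecording:
    """A subject's gaze stream over one task sequence.

    Samples are stored as parallel numpy arrays (``t``, ``x``, ``y``,
    ``valid``) for speed; :attr:`samples` exposes them as a sequence of
    :class:`GazeSample`.  Timestamps must be strictly increasing.
    Coordinates of invalid samples are unconstrained and never read.
    """

    def __init__(
        self,
        subject_id: str,
        t: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        valid: np.ndarray,
        nominal_rate_hz: float = 50.0,
        screen: ScreenGeometry | None = None,
    ) -> None:
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        valid = np.asarray(valid, dtype=bool)
        if not (t.shape == x.shape == y.shape == valid.shape) or t.ndim != 1:
            raise ValidationError("t, x, y, valid must be equal-length 1-D arrays")
        if nominal_rate_hz <= 0:
            raise ValidationError("nominal_rate_hz must be positive")
        if t.size:
            if t[0] < 0 or not np.all(np.isfinite(t)):
                raise DataError("timestamps must be finite and non-negative")
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                raise DataError(
                    f"timestamps not strictly increasing at row {bad[0] + 1} "
                    f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
                )
            v = valid
            if v.any():
                xv, yv = x[v], y[v]
                if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
                    raise DataError("valid samples with non-finite coordinates")
                if xv.size and (
                    xv.min() < 0 or xv.max() > 1 or yv.min() < 0 or yv.max() > 1
                ):
                    raise DataError("valid sample coordinates outside [0,1]")
        self.subject_id = str(subject_id)
        self.t = t
        self.x = x
        self.y = y
        self.valid = valid
        self.nominal_rate_hz = float(nominal_rate_hz)
        self.screen = screen if screen is not None else ScreenGeometry()

    @classmethod
    def from_samples(
        cls,
        subject_id: str,
        samples: Sequence[GazeSample],
        nominal_rate_hz: float = 50.0,
        screen: ScreenGeometry | None = None,
    ) -> "GazeRecording":
        t = np.array([s.t for s in samples], dtype=float)
        x = np.array([s.x for s in samples], dtype=float)
        y = np.array([s.y for s in samples], dtype=float)
        v = np.array([s.valid for s in samples], dtype=bool)
        return cls(subject_id, t, x, y, v, nominal_rate_hz, screen)

    @property
    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(float(t), float(x), float(y), bool(v))
            if v
            else GazeSample(float(t), float("nan"), float("nan"), False)
            for t, x, y, v in zip(self.t, self.x, self.y, self.valid)
        ]

    def __len__(self) -> int:
        return int(self.t.size)

    def __iter__(self) -> Iterator[GazeSample]:
        return iter(self.samples)

    @property
    def sampling_period(self) -> float:
        """Nominal seconds per sample (1 / nominal_rate_hz)."""
        return 1.0 / self.nominal_rate_hz

    def equals(self, other: "GazeRecording") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.nominal_rate_hz == other.nominal_rate_hz
            and len(self) == len(other)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.valid, other.valid)
            and np.array_equal(self.x[self.valid], other.x[other.valid])
            and np.array_equal(self.y[self.valid], other.y[other.valid])
        )


def _check_clinical_range(name: str, value: float | None, lo: float, hi: float) -> None:
    if value is not None and not (lo <= value <= hi):
        raise ValidationError(f"{name} must be in [{lo}, {hi}], got {value}")


@dataclass
class SubjectRecord:
    """Clinical metadata for one subject, joined later with the
    eye-tracking score.

    ``mmse`` 0–30 (lower = more impaired), ``adas_cog`` 0–70 (higher =
    more impaired), ``fab`` 0–18 (lower = more impaired), ``cdr`` in
    {0, 0.5, 1, 2, 3}.  ``None`` means not assessed.
    """

    subject_id: str
    group: Group
    mmse: int | None = None
    adas_cog: float | None = None
    fab: float | None = None
    cdr: float | None = None
    et_score: float | None = None
    recording_efficiency: float | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.mmse is not None:
            self.mmse = int(self.mmse)
        _check_clinical_range("mmse", self.mmse, 0, 30)
        _check_clinical_range("adas_cog", self.adas_cog, 0, 70)
        _check_clinical_range("fab", self.fab, 0, 18)
        if self.cdr is not None and float(self.cdr) not in CDR_LEVELS:
            raise ValidationError(f"cdr must be one of {CDR_LEVELS}, got {self.cdr}")
        _check_clinical_range("et_score", self.et_score, 0, 100)
        _check_clinical_range("recording_efficiency", self.recording_efficiency, 0, 1)


@dataclass
class Cohort:
    """An ordered collection of subjects with unique IDs."""

    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataError(f"duplicate subject_id: {dup!r}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def group_sizes(self) -> dict[Group, int]:
        sizes: dict[Group, int] = {}
        for s in self.subjects:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a pandas DataFrame (missing values as NaN)."""
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group.value,
                    "mmse": np.nan if s.mmse is None else s.mmse,
                    "adas_cog": np.nan if s.adas_cog is None else s.adas_cog,
                    "fab": np.nan if s.fab is None else s.fab,
                    "cdr": np.nan if s.cdr is None else s.cdr,
                    "et_score": np.nan if s.et_score is None else s.et_score,
                    "recording_efficiency": np.nan
                    if s.recording_efficiency is None
                    else s.recording_efficiency,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "group",
                "mmse",
                "adas_cog",
                "fab",
                "cdr",
                "et_score",
                "recording_efficiency",
            ],
        )


# ---------------------------------------------------------------------------
# Gaze log I/O: UTF-8 delimited text, header t,x,y,valid, valid in {0,1}.
# Coordinates are normalized by default; pass pixels=True to divide by the
# screen dimensions on read.
# ---------------------------------------------------------------------------

_GAZE_COLUMNS = ["t", "x", "y", "valid"]


def read_gaze_log(
    path,
    screen: ScreenGeometry | None = None,
    subject_id: str | None = None,
    nominal_rate_hz: float = 50.0,
    pixels: bool = False,
) -> GazeRecording:
    """Read a gaze log.

    Out-of-range coordinates on valid samples raise :class:`DataError`
    (never silently clamped); non-monotone timestamps raise naming the
    first offending row.
    """
    screen = screen if screen is not None else ScreenGeometry()
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse gaze log {path}: {exc}") from exc
    missing = [c for c in _GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gaze log {path} missing columns: {missing}")
    try:
        t = df["t"].to_numpy(dtype=float)
        x = df["x"].to_numpy(dtype=float)
        y = df["y"].to_numpy(dtype=float)
        valid_raw = df["valid"].to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"gaze log {path} has non-numeric cells: {exc}") from exc
    vals = np.unique(valid_raw)
    if not np.all(np.isin(vals, [0, 1])):
        raise FormatError(f"gaze log {path}: 'valid' must be 0 or 1, saw {vals!r}")
    valid = valid_raw.astype(bool)
    if pixels:
        x = x / screen.width_px
        y = y / screen.height_px
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    try:
        return GazeRecording(subject_id, t, x, y, valid, nominal_rate_hz, screen)
    except DataError as exc:
        raise DataError(f"gaze log {path}: {exc}") from exc


def write_gaze_log(recording: GazeRecording, path) -> None:
    """Write a gaze log re-readable by :func:`read_gaze_log`.

    Floats are written with full round-trip precision, so read-after-
    write reproduces the recording exactly.  Coordinates of invalid
    samples are written as 0 (they carry no information).
    """
    x = np.where(recording.valid, recording.x, 0.0)
    y = np.where(recording.valid, recording.y, 0.0)
    df = pd.DataFrame(
        {
            "t": recording.t,
            "x": x,
            "y": y,
            "valid": recording.valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort table I/O: header subject_id,group,mmse,adas_cog,fab,cdr
# (et_score / recording_efficiency optional); empty cell = missing.
# ---------------------------------------------------------------------------

_COHORT_REQUIRED = ["subject_id", "group"]
_COHORT_OPTIONAL = ["mmse", "adas_cog", "fab", "cdr", "et_score", "recording_efficiency"]


def _cell(row, col) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def read_cohort(path) -> Cohort:
    """Read a cohort table; missing clinical cells stay missing."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse cohort table {path}: {exc}") from exc
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table {path} missing columns: {missing}")
    subjects = []
    for _, row in df.iterrows():
        mmse = _cell(row, "mmse")
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=Group.parse(row["group"]),
                    mmse=None if mmse is None else int(round(mmse)),
                    adas_cog=_cell(row, "adas_cog"),
                    fab=_cell(row, "fab"),
                    cdr=_cell(row, "cdr"),
                    et_score=_cell(row, "et_score"),
                    recording_efficiency=_cell(row, "recording_efficiency"),
                )
            )
        except ValidationError as exc:
            raise DataError(f"cohort table {path}, subject {row['subject_id']}: {exc}") from exc
    return Cohort(subjects)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort table re-readable by :func:`read_cohort`."""
    cohort.to_frame().to_csv(path, index=False)
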