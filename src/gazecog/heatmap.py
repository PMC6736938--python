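"""Duration-based gaze heatmaps.

Each valid sample in the requested time window deposits one nominal
sampling period of dwell time into the grid cell containing it, so a
histogram-mode grid's total mass equals the valid dwell time in the
window.  Optional Gaussian smoothing (reflected boundaries, followed by
renormalization) preserves that total, which keeps the grid's ROI-mass
fraction exactly equal to the scoring module's task fraction whenever
the grid is aligned to the ROI edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .gaze_model import GazeRecording
from .task_schema import ROI

__all__ = ["DwellGrid", "duration_heatmap"]


@dataclass(frozen=True)
class DwellGrid:
    """Dwell-time grid over the unit square.

    ``values[r, c]`` is seconds of valid gaze in row r (top to bottom,
    matching the y-down screen convention), column c.  ``qc_note`` is
    non-empty when the window contained no valid samples.
    """

    values: np.ndarray
    window: tuple[float, float]
    qc_note: str = ""

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def total_dwell(self) -> float:
        return float(self.values.sum())

    def roi_mass_fraction(self, roi: ROI) -> float | None:
        """Fraction of grid mass inside ``roi``.

        Cells are attributed by their center; with the grid aligned to
        the ROI edges this equals the scoring fraction in histogram
        mode.  ``None`` when the grid is empty.
        """
        total = self.total_dwell
        if total == 0.0:
            return None
        cx = (np.arange(self.cols) + 0.5) / self.cols
        cy = (np.arange(self.rows) + 0.5) / self.rows
        xs, ys = np.meshgrid(cx, cy)
        mask = roi.contains(xs, ys)
        return float(self.values[mask].sum()) / total


def duration_heatmap(
    recording: GazeRecording,
    window: tuple[float, float],
    rows: int = 32,
    cols: int = 40,
    smooth_sigma: float = 0.0,
) -> DwellGrid:
    """Accumulate valid dwell time in ``window`` onto a rows x cols grid.

    ``smooth_sigma`` is a Gaussian kernel width in cell units; 0 gives
    the raw histogram.  Smoothing uses reflected boundaries and the
    result is rescaled to the pre-smoothing total mass.
    """
    if rows < 1 or cols < 1:
        raise ValidationError("rows and cols must be >= 1")
    if smooth_sigma < 0:
        raise ValidationError("smooth_sigma must be >= 0")
    start, end = window
    if not start < end:
        raise ValidationError(f"window must satisfy start < end, got {window}")
    sel = (recording.t >= start) & (recording.t < end) & recording.valid
    x = recording.x[sel]
    y = recording.y[sel]
    values = np.zeros((rows, cols), dtype=float)
    qc_note = ""
    if x.size == 0:
        qc_note = "no valid samples in window"
    else:
        # half-open cell edges; the right/bottom screen edge (coordinate
        # exactly 1.0) folds into the last cell
        ci = np.minimum((x * cols).astype(int), cols - 1)
        ri = np.minimum((y * rows).astype(int), rows - 1)
        np.add.at(values, (ri, ci), recording.sampling_period)
    if smooth_sigma > 0 and values.sum() > 0:
        total = values.sum()
        values = gaussian_filter(values, sigma=smooth_sigma, mode="reflect")
        s = values.sum()
        if s > 0:
            values *= total / s
    return DwellGrid(values=values, window=(float(start), float(end)), qc_note=qc_note)
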