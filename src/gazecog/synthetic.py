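"""Synthetic gaze recordings and cohorts.

The generator is a statistical stand-in for device recordings: it
reproduces the structure the scoring statistic depends on, not saccade
kinematics.  During each scored CHOICE window the gaze alternates
between an on-target state (ROI center plus Gaussian jitter, kept
inside the ROI) and an off-target state (uniform over the non-ROI part
of the screen), with independent exponential dwell times in each state.
For exponential dwells the long-run fraction of time on target — the
occupancy — has the closed form

    p_target = mean_dwell_on / (mean_dwell_on + mean_dwell_off),

which makes occupancy an exact oracle for the scoring fraction.  The
process is also the two-state continuous-time Markov chain with leave
rates 1/mean_dwell_on and 1/mean_dwell_off, whose indicator
autocovariance decays at rate (1/mean_dwell_on + 1/mean_dwell_off);
that gives the Monte-Carlo interval used by the parameter-recovery
checks (see :func:`occupancy_se`).

Outside CHOICE windows the gaze follows a center-biased AR(1) walk
(unscored, present so heatmaps and efficiency look plausible).
Tracking loss — blinks, looking away — arrives as a Poisson process of
episodes with exponential durations; samples inside an episode are
flagged invalid.  The long-run invalid fraction is
1 - exp(-loss_rate * mean_loss), the busy probability of an M/G/inf
queue.

Group-level defaults follow the three-group clinical design: healthy
controls, mild cognitive impairment, dementia, with group sizes
27/26/27 and MMSE means (SD) 28.7 (1.6) / 25.7 (3.0) / 16.0 (4.4).
Group target occupancies 0.75 / 0.55 / 0.35 are free parameters chosen
to give clear but overlapping score separation; they are not estimates
of any published quantity.  Within a group, a subject's occupancy is
shifted by ``coupling_weight`` x 0.1 x (their MMSE z-score), coupling
the gaze score to MMSE so rank correlations are tunable.

Per-subject RNG streams are spawned from the master seed keyed by
subject index, so adding a subject never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError
from .gaze_model import Cohort, GazeRecording, Group, ScreenGeometry, SubjectRecord
from .task_schema import ROI, SegmentKind, TaskTimeline, build_default_timeline

__all__ = [
    "SimulationParams",
    "GroupParams",
    "simulate_recording",
    "simulate_cohort",
    "default_group_params",
    "occupancy_se",
    "DEFAULT_N_PER_GROUP",
]

#: Default cohort composition: HC / MCI / dementia.
DEFAULT_N_PER_GROUP = (27, 26, 27)

# just inside the unit square so half-open containment never drops the edge
_EDGE = 1.0 - 1e-9


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one subject's gaze behavior.

    ``p_target`` is the long-run on-target occupancy; the exponential
    dwell means must satisfy
    p_target = mean_dwell_on / (mean_dwell_on + mean_dwell_off)
    (checked at construction; use :meth:`from_occupancy` to derive the
    off-dwell automatically).  The degenerate occupancies 0 and 1 are
    encoded by a zero dwell mean on the never-visited side.
    """

    p_target: float
    mean_dwell_on: float
    mean_dwell_off: float
    jitter_sd: float = 0.03
    loss_rate: float = 0.1
    mean_loss: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_target <= 1.0):
            raise ConfigError(f"p_target must be in [0,1], got {self.p_target}")
        if self.jitter_sd < 0 or self.loss_rate < 0 or self.mean_loss <= 0:
            raise ConfigError("jitter_sd, loss_rate must be >= 0; mean_loss > 0")
        if self.mean_dwell_on < 0 or self.mean_dwell_off < 0:
            raise ConfigError("dwell means must be non-negative")
        tot = self.mean_dwell_on + self.mean_dwell_off
        if tot <= 0:
            raise ConfigError("at least one dwell mean must be positive")
        implied = self.mean_dwell_on / tot
        if abs(implied - self.p_target) > 1e-9:
            raise ConfigError(
                f"dwell means imply occupancy {implied:.6f}, "
                f"inconsistent with p_target={self.p_target}"
            )

    @classmethod
    def from_occupancy(
        cls,
        p_target: float,
        mean_dwell_on: float = 1.0,
        jitter_sd: float = 0.03,
        loss_rate: float = 0.1,
        mean_loss: float = 0.25,
        seed: int = 0,
    ) -> "SimulationParams":
        """Build params from a target occupancy, deriving the off-dwell
        mean from a fixed on-dwell mean (both scale with dwell tempo,
        occupancy does not)."""
        if not (0.0 <= p_target <= 1.0):
            raise ConfigError(f"p_target must be in [0,1], got {p_target}")
        if p_target == 0.0:
            on, off = 0.0, max(mean_dwell_on, 1e-12)
        elif p_target == 1.0:
            on, off = max(mean_dwell_on, 1e-12), 0.0
        else:
            on = mean_dwell_on
            off = mean_dwell_on * (1.0 - p_target) / p_target
        return cls(p_target, on, off, jitter_sd, loss_rate, mean_loss, seed)

    @property
    def switch_rate(self) -> float:
        """Sum of the two state-leave rates; the indicator
        autocovariance decays at this rate."""
        if self.mean_dwell_on == 0 or self.mean_dwell_off == 0:
            return math.inf
        return 1.0 / self.mean_dwell_on + 1.0 / self.mean_dwell_off


def occupancy_se(params: SimulationParams, window_seconds: float) -> float:
    """Asymptotic standard error of the time-average occupancy over a
    window of the given length.

    For the two-state Markov process the indicator autocovariance is
    p(1-p) exp(-r |u|) with r = switch_rate, so
    Var(mean over T) ~= 2 p (1-p) / (r T).
    """
    p = params.p_target
    r = params.switch_rate
    if not math.isfinite(r):
        return 0.0
    return math.sqrt(2.0 * p * (1.0 - p) / (r * window_seconds))


@dataclass(frozen=True)
class GroupParams:
    """Per-clinical-group generative parameters: gaze behavior plus the
    MMSE distribution (truncated to [0, 30], rounded to integers)."""

    group: Group
    sim: SimulationParams
    mmse_mean: float
    mmse_sd: float

    def __post_init__(self) -> None:
        if self.mmse_sd < 0:
            raise ConfigError("mmse_sd must be >= 0")


def default_group_params() -> list[GroupParams]:
    """The three-group study conditions used throughout the test suite."""
    return [
        GroupParams(Group.HC, SimulationParams.from_occupancy(0.75), 28.7, 1.6),
        GroupParams(Group.MCI, SimulationParams.from_occupancy(0.55), 25.7, 3.0),
        GroupParams(Group.DEMENTIA, SimulationParams.from_occupancy(0.35), 16.0, 4.4),
    ]


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------


def _renewal_states(
    rng: np.random.Generator, duration: float, on: float, off: float, p: float
) -> tuple[np.ndarray, np.ndarray]:
    """Change-point times and states of the alternating renewal process
    over [0, duration).  Returns (start_times, states) with states[i]
    holding on [start_times[i], start_times[i+1])."""
    if on == 0.0:
        return np.array([0.0]), np.array([False])
    if off == 0.0:
        return np.array([0.0]), np.array([True])
    state = bool(rng.random() < p)  # stationary initial state
    chunk_t = [np.array([0.0])]
    chunk_s = [np.array([state])]
    t = 0.0
    s = state
    # draw alternating dwells in batches until the window is covered
    while t < duration:
        n = max(16, int(2.0 * duration / (on + off)) + 16)
        k = np.arange(n)
        even = k % 2 == 0
        means = np.where(even, on if s else off, off if s else on)
        cum = t + np.cumsum(rng.exponential(means))
        # change i happens at cum[i]; the state after it alternates
        # starting from (not s)
        after = (k % 2 == 1) == s
        chunk_t.append(cum)
        chunk_s.append(after)
        t = float(cum[-1])
        s = bool(after[-1])
    st = np.concatenate(chunk_t)
    sv = np.concatenate(chunk_s)
    keep = st < duration
    return st[keep], sv[keep]


def _states_at(sample_t: np.ndarray, starts: np.ndarray, states: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(starts, sample_t, side="right") - 1
    return states[np.clip(idx, 0, len(states) - 1)]


def _on_target_positions(
    rng: np.random.Generator, n: int, roi: ROI, jitter_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = roi.center
    x = np.clip(rng.normal(cx, jitter_sd, n), roi.x0, np.nextafter(roi.x1, 0))
    y = np.clip(rng.normal(cy, jitter_sd, n), roi.y0, np.nextafter(roi.y1, 0))
    return x, y


def _off_target_positions(
    rng: np.random.Generator, n: int, roi: ROI
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform over the unit square minus the ROI (rejection sampling)."""
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        m = max(16, int((n - filled) * 1.8))
        x = rng.random(m) * _EDGE
        y = rng.random(m) * _EDGE
        ok = ~roi.contains(x, y)
        take = min(int(ok.sum()), n - filled)
        xs[filled : filled + take] = x[ok][:take]
        ys[filled : filled + take] = y[ok][:take]
        filled += take
    return xs, ys


def _neutral_walk(
    rng: np.random.Generator, n: int, sd: float = 0.12, phi: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Center-biased AR(1) gaze walk with stationary SD ``sd``."""
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    out = []
    for _ in range(2):
        e = rng.normal(0.0, innov_sd, n)
        start = rng.normal(0.0, sd)
        z = lfilter([1.0], [1.0, -phi], e, zi=np.array([phi * start]))[0]
        out.append(np.clip(0.5 + z, 0.0, _EDGE))
    return out[0], out[1]


def simulate_recording(
    params: SimulationParams,
    timeline: TaskTimeline | None = None,
    subject_id: str = "sim",
    rng: np.random.Generator | None = None,
    nominal_rate_hz: float = 50.0,
    screen: ScreenGeometry | None = None,
) -> GazeRecording:
    """Simulate one recording over the timeline at the nominal rate.

    Deterministic for a fixed ``params.seed`` (or caller-supplied
    ``rng``): the same inputs always produce an identical recording.
    """
    timeline = timeline if timeline is not None else build_default_timeline()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    start, end = timeline.span
    dt = 1.0 / nominal_rate_hz
    n = int(round((end - start) * nominal_rate_hz))
    t = start + np.arange(n) * dt
    x = np.full(n, 0.5)
    y = np.full(n, 0.5)

    for seg in timeline.segments:
        sel = (t >= seg.onset) & (t < seg.offset)
        m = int(sel.sum())
        if m == 0:
            continue
        if seg.kind is SegmentKind.CHOICE and seg.target_roi is not None:
            starts, states = _renewal_states(
                rng, seg.duration, params.mean_dwell_on, params.mean_dwell_off,
                params.p_target,
            )
            on = _states_at(t[sel] - seg.onset, starts, states)
            sx = np.empty(m)
            sy = np.empty(m)
            n_on = int(on.sum())
            if n_on:
                sx[on], sy[on] = _on_target_positions(
                    rng, n_on, seg.target_roi, params.jitter_sd
                )
            if m - n_on:
                sx[~on], sy[~on] = _off_target_positions(rng, m - n_on, seg.target_roi)
            x[sel], y[sel] = sx, sy
        else:
            x[sel], y[sel] = _neutral_walk(rng, m)

    valid = np.ones(n, dtype=bool)
    if params.loss_rate > 0:
        # include a lead-in so episodes already in progress at the first
        # sample are represented (stationary loss process over the span)
        lead = 10.0 * params.mean_loss
        span = (end - start) + lead
        n_ep = rng.poisson(params.loss_rate * span)
        if n_ep:
            ep_start = (start - lead) + rng.random(n_ep) * span
            ep_len = rng.exponential(params.mean_loss, n_ep)
            lo = np.searchsorted(t, ep_start, side="left")
            hi = np.searchsorted(t, ep_start + ep_len, side="left")
            for a, b in zip(lo, hi):
                valid[a:b] = False
    return GazeRecording(
        subject_id, t, x, y, valid, nominal_rate_hz,
        screen if screen is not None else ScreenGeometry(),
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _truncated_mmse(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Integer MMSE from a normal truncated to [0, 30] (redraw)."""
    if sd == 0:
        return int(round(min(max(mean, 0.0), 30.0)))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 30.0:
            return int(round(v))
    return int(round(min(max(mean, 0.0), 30.0)))


def simulate_cohort(
    group_params_list: list[GroupParams] | None = None,
    n_per_group: tuple[int, ...] = DEFAULT_N_PER_GROUP,
    seed: int = 0,
    timeline: TaskTimeline | None = None,
    coupling_weight: float = 0.5,
    subject_sd: float = 0.08,
    nominal_rate_hz: float = 50.0,
) -> tuple[Cohort, dict[str, GazeRecording]]:
    """Simulate a full cohort: clinical table plus one recording per
    subject.

    A subject's occupancy is the group occupancy, plus
    coupling_weight x 0.1 x (their MMSE z-score), plus an independent
    N(0, subject_sd) heterogeneity term, clipped to [0.02, 0.98].
    ``coupling_weight`` is the within-group MMSE-gaze correlation knob
    (0 for independence); ``subject_sd`` is between-subject variation
    the clinical score does not explain, and is what keeps the group
    score distributions overlapping rather than cleanly separated.
    Per-subject RNG streams are spawned from ``seed`` keyed by global
    subject index, so cohorts are reproducible and insertion-order
    independent.
    """
    group_params_list = (
        group_params_list if group_params_list is not None else default_group_params()
    )
    if len({gp.group for gp in group_params_list}) != len(group_params_list):
        raise ConfigError("groups must be distinct")
    if len(n_per_group) != len(group_params_list):
        raise ConfigError("n_per_group length must match group_params_list")
    timeline = timeline if timeline is not None else build_default_timeline()
    subjects: list[SubjectRecord] = []
    recordings: dict[str, GazeRecording] = {}
    idx = 0
    for gp, n in zip(group_params_list, n_per_group):
        for k in range(n):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
            rng = np.random.default_rng(ss)
            sid = f"{gp.group.value}-{k + 1:03d}"
            mmse = _truncated_mmse(rng, gp.mmse_mean, gp.mmse_sd)
            z = 0.0 if gp.mmse_sd == 0 else (mmse - gp.mmse_mean) / gp.mmse_sd
            hetero = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
            p = float(
                np.clip(
                    gp.sim.p_target + coupling_weight * 0.1 * z + hetero, 0.02, 0.98
                )
            )
            sim = SimulationParams.from_occupancy(
                p,
                mean_dwell_on=gp.sim.mean_dwell_on if gp.sim.mean_dwell_on > 0 else 1.0,
                jitter_sd=gp.sim.jitter_sd,
                loss_rate=gp.sim.loss_rate,
                mean_loss=gp.sim.mean_loss,
                seed=gp.sim.seed,
            )
            rec = simulate_recording(
                sim, timeline, subject_id=sid, rng=rng,
                nominal_rate_hz=nominal_rate_hz,
            )
            subjects.append(SubjectRecord(subject_id=sid, group=gp.group, mmse=mmse))
            recordings[sid] = rec
            idx += 1
    return Cohort(subjects), recordings
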