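"""Velocity, rest/movement classification, bout segmentation, onset detection.

Velocity is computed frame-by-frame from the tracked centroid, median-filtered
over 1 s, and downsampled to 5 Hz (within-bin mean).  Rest is velocity
<= 0.5 cm/s; a movement bout is a maximal run of 5 Hz bins above that
threshold.  Movement onsets are detected at tracking rate with the
displacement / smoothing / duration / pre-rest rules: velocity is zeroed at
frames where the centroid does not move more than 1 cm within the next 1 s
(suppressing in-place dither), smoothed with a 167 ms moving average, and an
onset is the first frame of every maximal run with v > 0.5 cm/s lasting at
least 2 s whose preceding 4 s are entirely at or below 0.5 cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session_io import AlignedGrid, TrackingData

#: rest/movement velocity threshold, cm/s (v == threshold classifies as rest)
V_THRESH = 0.5


@dataclass
class LocomotionTrace:
    """Calibrated velocity at 5 Hz plus the raw tracking-rate velocity."""

    velocity: np.ndarray  # cm/s at 5 Hz
    raw_velocity: np.ndarray  # cm/s at tracking rate
    valid: np.ndarray  # per 5 Hz bin
    bin_duration: float
    t_start: float

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t_start + np.arange(self.velocity.size) * self.bin_duration


@dataclass
class OnsetParams:
    displacement_min: float = 1.0  # cm
    lookahead: float = 1.0  # s
    smooth_window: float = 5.0 / 30.0  # s (~167 ms; 5 frames at 30 fps)
    v_thresh: float = V_THRESH  # cm/s
    min_move: float = 2.0  # s
    min_pre_rest: float = 4.0  # s

    def __post_init__(self) -> None:
        for name in (
            "displacement_min",
            "lookahead",
            "smooth_window",
            "v_thresh",
            "min_move",
            "min_pre_rest",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochSet:
    """Rest/move partition of the session at 5 Hz."""

    labels: np.ndarray  # per-bin: True = move, False = rest (invalid bins excluded)
    valid: np.ndarray
    bin_duration: float
    t_start: float
    rest_intervals: list[tuple[float, float]] = field(default_factory=list)
    move_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def bouts(self) -> list[tuple[float, float]]:
        """Movement bouts: maximal move intervals, ``[start, end)`` seconds."""
        return self.move_intervals

    @property
    def n_bouts(self) -> int:
        return len(self.move_intervals)

    @property
    def mean_bout_length(self) -> float:
        if not self.move_intervals:
            return float("nan")
        return float(np.mean([e - s for s, e in self.move_intervals]))

    @property
    def rest_time(self) -> float:
        return float(np.sum(~self.labels & self.valid) * self.bin_duration)

    @property
    def move_time(self) -> float:
        return float(np.sum(self.labels & self.valid) * self.bin_duration)

    @property
    def fraction_rest(self) -> float:
        total = self.rest_time + self.move_time
        return self.rest_time / total if total > 0 else float("nan")

    def frames(self, state: str) -> np.ndarray:
        """Indices of valid 5 Hz bins in the given state ('rest'|'move'|'all')."""
        if state == "all":
            return np.flatnonzero(self.valid)
        if state == "rest":
            return np.flatnonzero(~self.labels & self.valid)
        if state == "move":
            return np.flatnonzero(self.labels & self.valid)
        raise ValueError(f"unknown state {state!r}")


def compute_velocity(tracking: TrackingData) -> np.ndarray:
    """Frame-by-frame centroid speed in cm/s at tracking rate.

    ``v[t] = cm_per_px * ||pos[t] - pos[t-1]|| / (ts[t] - ts[t-1])``; the
    first frame has v = 0.
    """
    dx = np.diff(tracking.x_px)
    dy = np.diff(tracking.y_px)
    dt = np.diff(tracking.timestamps)
    if np.any(dt <= 0):
        raise ValueError("tracking timestamps must be strictly increasing for velocity")
    v = np.zeros(tracking.timestamps.size)
    v[1:] = tracking.cm_per_px * np.hypot(dx, dy) / dt
    return v


def median_filter_centered(x: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding median with edge truncation (shrinking window)."""
    x = np.asarray(x, dtype=float)
    half = window // 2
    s = pd.Series(x)
    out = s.rolling(window=2 * half + 1, center=True, min_periods=1).median()
    return out.to_numpy()


def filter_velocity(
    raw_velocity: np.ndarray,
    tracking: TrackingData,
    grid: AlignedGrid,
    median_window_s: float = 1.0,
) -> LocomotionTrace:
    """1 s centered median filter, then 5 Hz downsampling (within-bin mean).

    Bins without a tracking sample take the nearest-neighbor sample from the
    grid; bins the grid marks invalid get NaN velocity.
    """
    raw_velocity = np.asarray(raw_velocity, dtype=float)
    rate = tracking.rate
    window = max(1, int(round(median_window_s * rate)))
    filt = median_filter_centered(raw_velocity, window)

    sums = np.zeros(grid.n_bins)
    counts = np.zeros(grid.n_bins)
    mask = grid.track_bin >= 0
    np.add.at(sums, grid.track_bin[mask], filt[mask])
    np.add.at(counts, grid.track_bin[mask], 1.0)
    with np.errstate(invalid="ignore"):
        v5 = np.where(counts > 0, sums / np.maximum(counts, 1), filt[grid.track_ref])
    v5 = np.where(grid.valid, v5, np.nan)
    return LocomotionTrace(
        velocity=v5,
        raw_velocity=raw_velocity,
        valid=grid.valid.copy(),
        bin_duration=grid.bin_duration,
        t_start=grid.t_start,
    )


def classify_epochs(loco: LocomotionTrace, v_thresh: float = V_THRESH) -> EpochSet:
    """Partition 5 Hz bins into rest (v <= threshold) and movement (v > threshold).

    The boundary value classifies as rest, matching the strict ``> 0.5 cm/s``
    movement definition.  Invalid bins break runs and are excluded from all
    statistics.
    """
    v = loco.velocity
    valid = loco.valid & np.isfinite(v)
    move = np.where(valid, v > v_thresh, False)

    def _intervals(mask: np.ndarray) -> list[tuple[float, float]]:
        padded = np.r_[False, mask, False]
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        t0, bd = loco.t_start, loco.bin_duration
        return [(t0 + s * bd, t0 + e * bd) for s, e in zip(starts, ends)]

    return EpochSet(
        labels=move,
        valid=valid,
        bin_duration=loco.bin_duration,
        t_start=loco.t_start,
        rest_intervals=_intervals(~move & valid),
        move_intervals=_intervals(move & valid),
    )


def onset_filtered_velocity(
    tracking: TrackingData, params: OnsetParams | None = None
) -> np.ndarray:
    """Displacement-filtered, smoothed velocity at tracking rate.

    Rule 1: zero the velocity at frames where the centroid does not move more
    than ``displacement_min`` cm from its current location at any point over
    the next ``lookahead`` seconds.  Rule 2: smooth with a centered
    ``smooth_window`` moving average (edge truncation).
    """
    params = params or OnsetParams()
    v = compute_velocity(tracking)
    ts = tracking.timestamps
    x = tracking.x_px * tracking.cm_per_px
    y = tracking.y_px * tracking.cm_per_px
    n = ts.size
    out = v.copy()
    # for each frame, the farthest excursion within the lookahead window
    j_end = np.searchsorted(ts, ts + params.lookahead, side="right")
    for i in range(n):
        seg = slice(i + 1, j_end[i])
        if seg.start >= seg.stop:
            out[i] = 0.0
            continue
        disp2 = (x[seg] - x[i]) ** 2 + (y[seg] - y[i]) ** 2
        if disp2.max() <= params.displacement_min**2:
            out[i] = 0.0
    rate = tracking.rate
    window = max(1, int(round(params.smooth_window * rate)))
    half = window // 2
    smoothed = (
        pd.Series(out).rolling(window=2 * half + 1, center=True, min_periods=1).mean()
    )
    return smoothed.to_numpy()


def detect_onsets(
    tracking: TrackingData, params: OnsetParams | None = None
) -> np.ndarray:
    """Movement onset times (s) by the displacement/smoothing/duration rules.

    An onset is the first frame of every maximal run with v > ``v_thresh``
    lasting at least ``min_move`` seconds whose preceding ``min_pre_rest``
    seconds are entirely at or below ``v_thresh`` on the filtered trace.
    """
    params = params or OnsetParams()
    ts = tracking.timestamps
    if ts[-1] - ts[0] < params.min_pre_rest + params.min_move:
        warnings.warn("trace shorter than min_pre_rest + min_move; no onsets")
        return np.empty(0)
    v = onset_filtered_velocity(tracking, params)
    above = v > params.v_thresh
    padded = np.r_[False, above, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    onsets = []
    for s, e in zip(starts, ends):
        if ts[e - 1] - ts[s] + (ts[1] - ts[0]) < params.min_move:
            continue
        t_on = ts[s]
        pre = (ts >= t_on - params.min_pre_rest) & (ts < t_on)
        if not pre.any():
            continue  # run starts too close to the trace start
        if ts[pre][0] - (t_on - params.min_pre_rest) > 1.5 * (ts[1] - ts[0]):
            continue  # pre-rest window not fully covered by the trace
        if np.any(v[pre] > params.v_thresh):
            continue
        onsets.append(t_on)
    return np.asarray(onsets)
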