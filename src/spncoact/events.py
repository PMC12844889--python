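"""Ca2+ event detection on the normalized 5 Hz raster, and event statistics.

An event is a maximal run of 5 Hz bins with z >= threshold (default 2.5 SD
above the whole-trace baseline) lasting at least ``min_duration`` (default
1 s, i.e. 5 bins).  The event time is the midpoint between the time of the
run's maximum and the time of the preceding local minimum of the z-trace
(searching left from the run start; at the trace start the first sample is
taken as the minimum).  Amplitude is the run maximum in z-units; duration is
the time above threshold.  Supra-threshold runs separated by a single
sub-threshold bin are not merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedRaster


@dataclass
class EventDetectionParams:
    threshold: float = 2.5  # z-units
    min_duration: float = 1.0  # seconds

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if not self.min_duration > 0:
            raise ValueError("min_duration must be positive")

    def min_bins(self, bin_duration: float) -> int:
        n = self.min_duration / bin_duration
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("min_duration must be a positive multiple of bin_duration")
        return int(round(n))


@dataclass
class BinaryRaster:
    """Boolean activity matrix at 5 Hz: True exactly on the above-threshold
    spans of detected events (before any forward-smoothing)."""

    active: np.ndarray  # (n_cells, n_bins) bool
    bin_duration: float
    t_start: float

    @property
    def n_cells(self) -> int:
        return self.active.shape[0]

    @property
    def n_bins(self) -> int:
        return self.active.shape[1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open ``(start, end)`` index pairs."""
    padded = np.r_[False, mask, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def detect_events(
    z: np.ndarray,
    times: np.ndarray,
    params: EventDetectionParams | None = None,
    bin_duration: float = 0.2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Detect events in one cell's 5 Hz z-trace.

    Parameters
    ----------
    z
        Z-scored 5 Hz trace (NaN bins are treated as sub-threshold).
    times
        Bin start times in seconds, same length as ``z``.

    Returns
    -------
    events, active
        ``events`` has columns ``time_s, amplitude_z, duration_s``; ``active``
        is the boolean above-threshold span mask of the detected events.
    """
    params = params or EventDetectionParams()
    z = np.asarray(z, dtype=float)
    times = np.asarray(times, dtype=float)
    min_bins = params.min_bins(bin_duration)
    above = np.where(np.isnan(z), False, z >= params.threshold)
    active = np.zeros_like(above)
    rows = []
    for start, end in _runs(above):
        if end - start < min_bins:
            continue
        active[start:end] = True
        seg = z[start:end]
        peak = start + int(np.argmax(seg))
        # preceding local minimum: walk left from the run start while the
        # trace keeps decreasing leftwards; NaN stops the walk
        j = start
        while j > 0 and not np.isnan(z[j - 1]) and z[j - 1] < z[j]:
            j -= 1
        rows.append(
            {
                "time_s": 0.5 * (times[j] + times[peak]),
                "amplitude_z": float(z[peak]),
                "duration_s": (end - start) * bin_duration,
            }
        )
    events = pd.DataFrame(rows, columns=["time_s", "amplitude_z", "duration_s"])
    return events, active


def detect_events_raster(
    raster: NormalizedRaster, params: EventDetectionParams | None = None
) -> tuple[pd.DataFrame, BinaryRaster]:
    """Detect events for every cell of a normalized raster.

    Returns an event table with columns ``cell, time_s, amplitude_z,
    duration_s`` and the binary activity raster.
    """
    params = params or EventDetectionParams()
    times = raster.bin_starts
    active = np.zeros(raster.z.shape, dtype=bool)
    tables = []
    for i, cid in enumerate(raster.cell_ids):
        ev, act = detect_events(raster.z[i], times, params, raster.bin_duration)
        ev.insert(0, "cell", cid)
        tables.append(ev)
        active[i] = act
    events = pd.concat(tables, ignore_index=True)
    return events, BinaryRaster(
        active=active, bin_duration=raster.bin_duration, t_start=raster.t_start
    )


def events_to_raster(
    event_times: list[np.ndarray],
    n_bins: int,
    bin_duration: float = 0.2,
    t_start: float = 0.0,
    span: float = 1.0,
) -> BinaryRaster:
    """Build a binary raster from per-cell event times.

    Each event activates the bins covered by ``[t, t + span)``; used to turn
    ground-truth event trains into the same substrate the detector produces
    (whose above-threshold spans last about 1 s).
    """
    active = np.zeros((len(event_times), n_bins), dtype=bool)
    span_bins = max(1, int(round(span / bin_duration)))
    for i, ts in enumerate(event_times):
        idx = np.floor((np.asarray(ts, dtype=float) - t_start) / bin_duration).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        for k in idx:
            active[i, k : k + span_bins] = True
    return BinaryRaster(active=active, bin_duration=bin_duration, t_start=t_start)


def event_rate_by_velocity(
    events: pd.DataFrame,
    velocity: np.ndarray,
    bin_starts: np.ndarray,
    bin_edges: np.ndarray,
    n_cells: int,
    bin_duration: float = 0.2,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Average per-cell event rate in bins of animal velocity.

    For each velocity bin the rate is (events whose time falls in 5 Hz frames
    of that bin) / (total time spent in that bin), averaged across cells.
    Velocity bins with no occupancy are NaN (flagged, not zero).

    Returns a frame with columns ``v_lo, v_hi, time_s, n_events, rate``.
    """
    velocity = np.asarray(velocity, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if valid is None:
        valid = np.isfinite(velocity)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(velocity)
    vbin_of_frame = np.digitize(velocity, bin_edges) - 1
    n_vbins = bin_edges.size - 1
    in_range = (vbin_of_frame >= 0) & (vbin_of_frame < n_vbins) & valid

    occupancy = np.bincount(vbin_of_frame[in_range], minlength=n_vbins) * bin_duration

    counts = np.zeros(n_vbins)
    if len(events):
        frame = np.floor((events["time_s"].to_numpy() - bin_starts[0]) / bin_duration)
        frame = frame.astype(int)
        ok = (frame >= 0) & (frame < velocity.size)
        frame = frame[ok]
        sel = in_range[frame]
        counts = np.bincount(vbin_of_frame[frame[sel]], minlength=n_vbins).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / (occupancy * n_cells), np.nan)
    return pd.DataFrame(
        {
            "v_lo": bin_edges[:-1],
            "v_hi": bin_edges[1:],
            "time_s": occupancy,
            "n_events": counts,
            "rate": rate,
        }
    )


def event_prob_around_movement(
    events: pd.DataFrame,
    onsets: np.ndarray,
    window: tuple[float, float] = (-2.0, 2.5),
    bin_duration: float = 0.2,
    cell_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Probability of an event at each time offset around movement onsets.

    For each offset bin, the fraction of (cell, onset) pairs with at least one
    event in ``[onset + offset, onset + offset + bin_duration)``, i.e. the
    per-cell event probability aligned to movement onset.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("at least one movement onset is required")
    if cell_ids is None:
        cell_ids = sorted(events["cell"].unique()) if len(events) else []
    if not cell_ids:
        raise ValueError("no cells to align")
    offsets = np.arange(window[0], window[1] - 1e-9, bin_duration)
    hit = np.zeros((len(cell_ids), onsets.size, offsets.size), dtype=bool)
    by_cell = {c: g["time_s"].to_numpy() for c, g in events.groupby("cell")}
    for ci, cid in enumerate(cell_ids):
        ts = by_cell.get(cid, np.empty(0))
        for oi, onset in enumerate(onsets):
            rel = ts - onset
            k = np.floor((rel - window[0]) / bin_duration).astype(int)
            k = k[(k >= 0) & (k < offsets.size)]
            hit[ci, oi, k] = True
    prob = hit.reshape(-1, offsets.size).mean(axis=0)
    return pd.DataFrame({"offset_s": offsets, "prob": prob})


def event_amplitude_duration_summary(events: pd.DataFrame) -> dict:
    """Pooled and per-cell amplitude/duration summaries (means, SDs, histograms)."""
    if not len(events):
        return {"pooled": {}, "per_cell": {}, "n_events": 0}
    pooled = {}
    for col, name in [("amplitude_z", "amplitude"), ("duration_s", "duration")]:
        x = events[col].to_numpy()
        counts, edges = np.histogram(x, bins="auto")
        pooled[name] = {
            "mean": float(x.mean()),
            "sd": float(x.std()),
            "hist_counts": counts.tolist(),
            "hist_edges": edges.tolist(),
        }
    per_cell = (
        events.groupby("cell")[["amplitude_z", "duration_s"]]
        .agg(["mean", "std", "count"])
        .to_dict()
    )
    return {"pooled": pooled, "per_cell": per_cell, "n_events": int(len(events))}
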