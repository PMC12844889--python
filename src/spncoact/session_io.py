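"""Session file formats, validation, and miniscope/behavior stream alignment.

A session consists of three delimited-text streams that arrive on different
clocks: extracted per-cell fluorescence traces with per-frame timestamps
(~20 frames/s from the miniscope), cell centroid coordinates in the field of
view (µm), and centroid tracking of the animal (~30 frames/s, pixels).
Everything downstream operates on a common 5 Hz grid; :func:`align_streams`
builds that grid from the two timestamp streams.

Internal conventions: traces are stored cells-as-rows, distances in µm,
times in seconds.  On-disk timestamps are milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: duration of one bin of the common analysis grid, seconds (5 Hz)
BIN_DURATION = 0.2

#: tracking gaps longer than this (seconds) mark grid bins invalid
MAX_TRACKING_GAP = 0.5

#: numerical guard (seconds) so timestamps lying exactly on a bin edge are
#: assigned to the bin they open rather than leaking into the previous one
EDGE_EPS = 1e-9


@dataclass
class FluorescenceSession:
    """Raw cells x frames trace matrix at acquisition rate.

    Parameters
    ----------
    traces
        Real matrix, shape ``(n_cells, n_frames)``, arbitrary fluorescence units.
    timestamps
        Per-frame time in seconds, strictly increasing.
    acq_rate
        Nominal acquisition rate, frames/s.
    cell_ids
        One label per row of ``traces``.
    """

    traces: np.ndarray
    timestamps: np.ndarray
    acq_rate: float
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (cells x frames)")
        if self.traces.shape[1] != self.timestamps.size:
            raise ValueError(
                f"traces have {self.traces.shape[1]} frames but "
                f"{self.timestamps.size} timestamps"
            )
        if len(self.cell_ids) != self.traces.shape[0]:
            raise ValueError("one cell id required per trace row")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise ValueError(f"timestamps not strictly increasing at frame {bad}")
        if np.isnan(self.traces).any():
            cell, frame = np.argwhere(np.isnan(self.traces))[0]
            raise ValueError(
                f"missing value in traces: cell {self.cell_ids[cell]!r}, frame {frame}"
            )

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class CellMap:
    """Cell centroid coordinates in the field of view (µm)."""

    centroids: np.ndarray  # (n_cells, 2), µm
    fov: tuple[float, float]  # (width, height), µm
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("cell centroids must be finite")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i:04d}" for i in range(len(self.centroids))]
        if len(self.cell_ids) != len(self.centroids):
            raise ValueError("one centroid required per cell id")

    @property
    def n_cells(self) -> int:
        return len(self.centroids)


@dataclass
class TrackingData:
    """Behavioral tracking stream (ezTrack-style centroid output)."""

    frame: np.ndarray
    timestamps: np.ndarray  # seconds
    x_px: np.ndarray
    y_px: np.ndarray
    cm_per_px: float

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        n = self.timestamps.size
        if not (self.frame.size == self.x_px.size == self.y_px.size == n):
            raise ValueError("tracking columns have mismatched lengths")
        if n > 1 and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("tracking timestamps must be nondecreasing")
        if not self.cm_per_px > 0:
            raise ValueError("cm_per_px scale must be positive")

    @property
    def rate(self) -> float:
        """Median tracking frame rate, frames/s."""
        dt = np.median(np.diff(self.timestamps))
        return 1.0 / dt


@dataclass
class AlignedGrid:
    """Common 5 Hz frame grid spanning the miniscope/tracking overlap.

    Bins are half-open ``[t, t + bin_duration)`` anchored at the later of the
    two stream starts, so they partition the overlap with no double counting.
    """

    t_start: float
    n_bins: int
    bin_duration: float
    mini_bin: np.ndarray  # per miniscope frame: grid bin index, -1 outside overlap
    track_bin: np.ndarray  # per tracking sample: grid bin index, -1 outside
    track_ref: np.ndarray  # per bin: index of tracking sample used for position
    valid: np.ndarray  # per bin: False where the tracking gap exceeds MAX_TRACKING_GAP

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_bins) * self.bin_duration

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_duration / 2.0


def align_streams(
    session: FluorescenceSession,
    tracking: TrackingData,
    target_rate: float = 5.0,
    max_gap: float = MAX_TRACKING_GAP,
) -> AlignedGrid:
    """Bin both streams onto a common grid at ``target_rate``.

    The grid spans the temporal overlap of the two streams.  Each grid bin
    maps to the miniscope frames and tracking samples whose timestamps fall
    in ``[t, t + 1/target_rate)``; bins without a tracking sample inherit the
    nearest-neighbor position, and bins whose nearest sample is further than
    ``max_gap`` seconds are marked invalid.

    Raises
    ------
    ValueError
        If the temporal overlap is less than 50% of the shorter stream.
    """
    bd = 1.0 / target_rate
    mts, tts = session.timestamps, tracking.timestamps
    t0 = max(mts[0], tts[0])
    t_end = min(mts[-1], tts[-1])
    overlap = t_end - t0
    shorter = min(mts[-1] - mts[0], tts[-1] - tts[0])
    if shorter <= 0 or overlap < 0.5 * shorter:
        raise ValueError(
            f"streams overlap for {max(overlap, 0.0):.2f} s, "
            f"less than 50% of the shorter stream ({shorter:.2f} s)"
        )
    n_bins = int(np.floor((overlap + EDGE_EPS) / bd)) + 1

    def _assign(ts: np.ndarray) -> np.ndarray:
        idx = np.floor((ts - t0 + EDGE_EPS) / bd).astype(int)
        idx[(ts < t0) | (idx >= n_bins)] = -1
        return idx

    mini_bin = _assign(mts)
    track_bin = _assign(tts)

    centers = t0 + (np.arange(n_bins) + 0.5) * bd
    # nearest tracking sample to each bin center
    pos = np.searchsorted(tts, centers)
    left = np.clip(pos - 1, 0, tts.size - 1)
    right = np.clip(pos, 0, tts.size - 1)
    use_right = np.abs(tts[right] - centers) < np.abs(tts[left] - centers)
    track_ref = np.where(use_right, right, left)

    has_sample = np.zeros(n_bins, dtype=bool)
    has_sample[track_bin[track_bin >= 0]] = True
    gap = np.abs(tts[track_ref] - centers)
    valid = has_sample | (gap <= max_gap)

    logger.info(
        "aligned %d miniscope frames and %d tracking samples onto %d bins "
        "(%d invalid)",
        int(np.sum(mini_bin >= 0)),
        int(np.sum(track_bin >= 0)),
        n_bins,
        int(np.sum(~valid)),
    )
    return AlignedGrid(
        t_start=float(t0),
        n_bins=n_bins,
        bin_duration=bd,
        mini_bin=mini_bin,
        track_bin=track_bin,
        track_ref=track_ref,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# on-disk formats (column contracts documented in the writer docstrings)
# ---------------------------------------------------------------------------

def save_session(
    outdir: str | Path,
    session: FluorescenceSession,
    cell_map: CellMap,
    tracking: TrackingData,
) -> Path:
    """Write a session to ``outdir`` as delimited text.

    Files written:

    - ``traces.csv`` — header row of cell ids, one row per miniscope frame;
    - ``timestamps.csv`` — column ``ts_ms``, one row per miniscope frame;
    - ``centroids.csv`` — columns ``cell, x_um, y_um``;
    - ``tracking.csv`` — columns ``frame, ts_ms, x_px, y_px``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(session.traces.T, columns=session.cell_ids).to_csv(
        outdir / "traces.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame({"ts_ms": session.timestamps * 1000.0}).to_csv(
        outdir / "timestamps.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {
            "cell": cell_map.cell_ids,
            "x_um": cell_map.centroids[:, 0],
            "y_um": cell_map.centroids[:, 1],
        }
    ).to_csv(outdir / "centroids.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "frame": tracking.frame,
            "ts_ms": tracking.timestamps * 1000.0,
            "x_px": tracking.x_px,
            "y_px": tracking.y_px,
        }
    ).to_csv(outdir / "tracking.csv", index=False, float_format="%.17g")
    return outdir


def load_session(
    indir: str | Path,
    cm_per_px: float,
    fov: tuple[float, float],
    acq_rate: float = 20.0,
) -> tuple[FluorescenceSession, CellMap, TrackingData]:
    """Load and validate a session written by :func:`save_session`.

    Raises
    ------
    ValueError
        On NaN traces (naming the cell and frame), mismatched cell ids
        between traces and centroids (naming the offending ids), or
        non-monotone timestamps.
    """
    indir = Path(indir)
    traces_df = pd.read_csv(indir / "traces.csv", float_precision="round_trip")
    ts = (
        pd.read_csv(indir / "timestamps.csv", float_precision="round_trip")["ts_ms"].to_numpy()
        / 1000.0
    )
    cent = pd.read_csv(indir / "centroids.csv", float_precision="round_trip")
    trk = pd.read_csv(indir / "tracking.csv", float_precision="round_trip")

    trace_ids = list(traces_df.columns)
    centroid_ids = list(cent["cell"].astype(str))
    missing = sorted(set(trace_ids) - set(centroid_ids))
    extra = sorted(set(centroid_ids) - set(trace_ids))
    if missing or extra:
        raise ValueError(
            "cell ids inconsistent between traces and centroids: "
            f"missing centroids for {missing}, centroids without traces {extra}"
        )
    # order centroids to match trace columns
    cent = cent.set_index(cent["cell"].astype(str)).loc[trace_ids]

    session = FluorescenceSession(
        traces=traces_df.to_numpy().T,
        timestamps=ts,
        acq_rate=acq_rate,
        cell_ids=trace_ids,
    )
    cell_map = CellMap(
        centroids=np.column_stack([cent["x_um"].to_numpy(), cent["y_um"].to_numpy()]),
        fov=fov,
        cell_ids=trace_ids,
    )
    tracking = TrackingData(
        frame=trk["frame"].to_numpy(),
        timestamps=trk["ts_ms"].to_numpy() / 1000.0,
        x_px=trk["x_px"].to_numpy(),
        y_px=trk["y_px"].to_numpy(),
        cm_per_px=cm_per_px,
    )
    logger.info(
        "loaded session: %d cells x %d frames, %d tracking rows",
        session.n_cells,
        session.n_frames,
        tracking.timestamps.size,
    )
    return session, cell_map, tracking
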