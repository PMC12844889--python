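"""Trace normalization: p99 scaling, z-scoring, and 5 Hz max-downsampling.

The pipeline order is scale -> z-score -> downsample-max.  Scaling by the
99th-percentile value makes the transform invariant to the arbitrary gain of
extracted fluorescence traces (scale followed by z-score cancels any positive
gain); z-scoring expresses each trace in units of its whole-session standard
deviation so that the event threshold (2.5 SD) is comparable across cells;
max-downsampling to 5 Hz preserves transient peaks that mean-downsampling
would dilute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_io import AlignedGrid, FluorescenceSession


@dataclass
class NormalizedRaster:
    """Per-cell scaled, z-scored, 5 Hz max-downsampled traces.

    ``z`` has shape ``(n_cells, n_bins)`` in z-score units; bins with no
    miniscope sample are NaN and flagged in ``valid``.  ``z_full`` keeps the
    pre-downsample z-scored trace at acquisition rate (per-cell mean 0, SD 1;
    the max-downsample shifts moments, so moment checks belong on ``z_full``).
    """

    z: np.ndarray
    bin_duration: float
    t_start: float
    cell_ids: list[str]
    valid: np.ndarray
    z_full: np.ndarray | None = None
    scale_factors: np.ndarray | None = None  # per-cell p99 of the raw trace
    moments: np.ndarray | None = None  # per-cell (mean, sd) of the scaled trace

    @property
    def n_cells(self) -> int:
        return self.z.shape[0]

    @property
    def n_bins(self) -> int:
        return self.z.shape[1]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_bins) * self.bin_duration


def scale_to_p99(trace: np.ndarray) -> np.ndarray:
    """Divide a trace by its 99th-percentile value (linear-interpolation quantile).

    Raises ``ValueError`` for a constant trace (degenerate cell) or a
    non-positive p99, for which the scaling is undefined.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0 or np.ptp(trace) == 0:
        raise ValueError("constant trace: p99 scaling undefined for a degenerate cell")
    p99 = np.percentile(trace, 99)
    if p99 <= 0:
        raise ValueError("99th percentile is not positive; cannot scale")
    return trace / p99


def zscore(trace: np.ndarray) -> np.ndarray:
    """Z-score a trace over the full session: (x - mean) / SD.

    Positive values correspond to fluorescence above the session mean.
    Raises ``ValueError`` if the SD is zero.
    """
    trace = np.asarray(trace, dtype=float)
    sd = trace.std()
    if sd == 0:
        raise ValueError("zero standard deviation: z-score undefined")
    return (trace - trace.mean()) / sd


def downsample_max(trace: np.ndarray, grid: AlignedGrid) -> np.ndarray:
    """Max-downsample an acquisition-rate trace onto the aligned 5 Hz grid.

    Each output bin is the maximum over the miniscope samples assigned to it;
    bins with no member sample are NaN.
    """
    return _downsample_max_matrix(np.asarray(trace, dtype=float)[None, :], grid)[0]


def _downsample_max_matrix(traces: np.ndarray, grid: AlignedGrid) -> np.ndarray:
    if traces.shape[1] != grid.mini_bin.size:
        raise ValueError("trace length does not match the grid's miniscope frame count")
    out = np.full((traces.shape[0], grid.n_bins), np.nan)
    mask = grid.mini_bin >= 0
    bins = grid.mini_bin[mask]
    vals = traces[:, mask]
    if bins.size == 0:
        return out
    # mini_bin is nondecreasing over frames; reduce over runs of equal bin index
    starts = np.flatnonzero(np.r_[True, np.diff(bins) != 0])
    out[:, bins[starts]] = np.maximum.reduceat(vals, starts, axis=1)
    return out


def normalize_session(
    session: FluorescenceSession, grid: AlignedGrid, keep_full: bool = True
) -> NormalizedRaster:
    """Apply scale -> z-score -> downsample-max to every cell of a session."""
    n_cells = session.n_cells
    z_full = np.empty_like(session.traces)
    scale_factors = np.empty(n_cells)
    moments = np.empty((n_cells, 2))
    for i in range(n_cells):
        scaled = scale_to_p99(session.traces[i])
        scale_factors[i] = np.percentile(session.traces[i], 99)
        moments[i] = scaled.mean(), scaled.std()
        z_full[i] = zscore(scaled)
    z = _downsample_max_matrix(z_full, grid)
    valid = ~np.isnan(z).any(axis=0)
    return NormalizedRaster(
        z=z,
        bin_duration=grid.bin_duration,
        t_start=grid.t_start,
        cell_ids=list(session.cell_ids),
        valid=valid,
        z_full=z_full if keep_full else None,
        scale_factors=scale_factors,
        moments=moments,
    )
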