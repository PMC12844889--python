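"""Distance-binned, shuffle-normalized pairwise Jaccard co-activity.

For every unordered cell pair the Jaccard index is computed on the
forward-smoothed binary activity rasters:

    J(a, b) = |frames where both active| / |frames where either active|

restricted to an optional frame subset (all frames, rest frames or movement
frames).  Pairs are grouped into half-open Euclidean-distance bins and each
bin's mean observed J is normalized by the mean J of a shuffle null in which
every cell's *unsmoothed* binary trace is independently circularly rotated in
time (preserving event count and run-length structure), passed through the
identical forward-smoothing, and re-scored.  The normalized profile is ~1 at
every distance when cells are independent, and falls with distance when
nearby cells are co-active above chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .events import BinaryRaster
from .session_io import CellMap

#: forward-smoothing window, seconds: each active bin also activates the next 1 s
FORWARD_SMOOTH_S = 1.0


@dataclass
class CoactivityParams:
    forward_smooth: float = FORWARD_SMOOTH_S  # s
    bin_width: float = 50.0  # µm (50 or 250 in practice)
    n_shuffles: int = 1000
    state_filter: str = "all"  # all | rest | move

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if self.state_filter not in ("all", "rest", "move"):
            raise ValueError("state_filter must be all, rest or move")


def forward_smooth(active: np.ndarray, window_bins: int = 5) -> np.ndarray:
    """Dilate activity forward in time: bin k activates bins k..k+window_bins.

    Clipped at the trace end.  Operates on (n_cells, n_bins) boolean arrays.
    """
    active = np.asarray(active, dtype=bool)
    out = active.copy()
    for s in range(1, window_bins + 1):
        out[..., s:] |= active[..., :-s]
    return out


def jaccard_matrix(
    active: np.ndarray, frames: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise Jaccard index matrix over an optional frame subset.

    Pairs with an empty union are NaN (undefined, excluded downstream).
    Requires at least two cells.
    """
    active = np.asarray(active, dtype=bool)
    if active.shape[0] < 2:
        raise ValueError("jaccard_matrix requires at least 2 cells")
    a = active if frames is None else active[:, frames]
    af = a.astype(np.float64)
    inter = af @ af.T
    counts = af.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), np.nan)
    return jac


def coactivity_rate_matrix(
    active: np.ndarray, frames: np.ndarray | None = None
) -> np.ndarray:
    """All-frames variant: co-active frame count divided by the number of
    frames scored (not the union).  Exposed as an option; the Jaccard
    denominator is the default statistic."""
    active = np.asarray(active, dtype=bool)
    a = active if frames is None else active[:, frames]
    af = a.astype(np.float64)
    n = a.shape[1]
    if n == 0:
        return np.full((a.shape[0], a.shape[0]), np.nan)
    return (af @ af.T) / n


def _rotate_rows(active: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Circularly rotate each row of ``active`` by its own offset."""
    n_cells, n_bins = active.shape
    idx = (np.arange(n_bins)[None, :] - offsets[:, None]) % n_bins
    return np.take_along_axis(active, idx, axis=1)


def shuffle_null(
    active: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    frames: np.ndarray | None = None,
    smooth_bins: int = 5,
    statistic: str = "jaccard",
) -> np.ndarray:
    """Per-pair mean Jaccard under independent circular time rotations.

    Each shuffle independently rotates every cell's *unsmoothed* binary trace
    by a uniform random offset, applies the identical forward smoothing, and
    recomputes the pairwise statistic; the mean over shuffles is returned.
    Rotation preserves each cell's event count and run-length structure, which
    is what the null must retain to control for activity level.
    """
    active = np.asarray(active, dtype=bool)
    n_cells, n_bins = active.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    score = jaccard_matrix if statistic == "jaccard" else coactivity_rate_matrix
    total = np.zeros((n_cells, n_cells))
    count = np.zeros((n_cells, n_cells))
    for _ in range(n_shuffles):
        offsets = rng.integers(0, n_bins, size=n_cells)
        rolled = _rotate_rows(active, offsets)
        smoothed = forward_smooth(rolled, smooth_bins)
        j = score(smoothed, frames)
        ok = np.isfinite(j)
        total[ok] += j[ok]
        count += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def pair_distances(cell_map: CellMap) -> np.ndarray:
    """Euclidean distance matrix between cell centroids, µm."""
    return squareform(pdist(cell_map.centroids))


def profile_by_distance(
    j_obs: np.ndarray,
    j_null: np.ndarray,
    cell_map: CellMap,
    bin_width: float = 50.0,
) -> pd.DataFrame:
    """Bin pairs by centroid distance and normalize observed by shuffled means.

    Pairs fall in half-open bins ``[k*w, (k+1)*w)``; the per-bin normalized
    value is (mean observed J) / (mean shuffled J).  Empty bins are omitted.

    Returns columns ``bin_lo, bin_center, n_pairs, observed, shuffle_mean,
    normalized``.
    """
    d = squareform(pdist(cell_map.centroids))
    iu = np.triu_indices(d.shape[0], k=1)
    dist = d[iu]
    obs = j_obs[iu]
    null = j_null[iu]
    ok = np.isfinite(obs) & np.isfinite(null)
    dist, obs, null = dist[ok], obs[ok], null[ok]
    if dist.size == 0:
        return pd.DataFrame(
            columns=["bin_lo", "bin_center", "n_pairs", "observed", "shuffle_mean", "normalized"]
        )
    bins = np.floor(dist / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        mean_null = null[sel].mean()
        mean_obs = obs[sel].mean()
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_center": (b + 0.5) * bin_width,
                "n_pairs": int(sel.sum()),
                "observed": mean_obs,
                "shuffle_mean": mean_null,
                "normalized": mean_obs / mean_null if mean_null > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def coactivity_profile(
    raster: BinaryRaster,
    cell_map: CellMap,
    params: CoactivityParams | None = None,
    frames: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Full distance profile from an *unsmoothed* binary event raster.

    Applies forward smoothing, computes observed pairwise Jaccard over the
    frame subset, builds the circular-rotation shuffle null through the same
    transform chain, and returns the distance-binned normalized profile.
    """
    params = params or CoactivityParams()
    smooth_bins = int(round(params.forward_smooth / raster.bin_duration))
    smoothed = forward_smooth(raster.active, smooth_bins)
    j_obs = jaccard_matrix(smoothed, frames)
    j_null = shuffle_null(
        raster.active,
        n_shuffles=params.n_shuffles,
        seed=seed,
        frames=frames,
        smooth_bins=smooth_bins,
    )
    return profile_by_distance(j_obs, j_null, cell_map, params.bin_width)
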