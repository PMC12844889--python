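"""Per-frame spatial coordination index (SCI).

For each 5 Hz frame, the Euclidean distances between all pairs of co-active
cells are compared against a shuffled null to ask whether co-active cells are
closer together (left-shifted distance distribution, "clustered") or farther
apart ("dispersed") than chance, via a pair of one-sided two-sample
Kolmogorov–Smirnov comparisons.  The index is -log10 of the smaller p-value,
signed positive when the clustered side wins, so larger SCI means more
spatially clustered co-activity; frames with no active pair score exactly 0.

Two null schemes are available:

``cell_permutation`` (default)
    The null draws are random subsets of the *cells* (same count as the
    frame's active cells); their pair distances are pooled into the null
    sample, and the p-value is the Monte Carlo permutation tail of the
    one-sided KS statistic across the draws.  Because the draws are
    exchangeable with a uniform random active subset, the p-values are
    calibrated by construction; pair distances within a frame are
    geometrically dependent (a cells carry only 2a coordinates), so a
    calibrated test must permute cells, not individual distances.

``distance_pool``
    Frame-sized distance sets are resampled from the full pairwise-distance
    list (without replacement within a draw), pooled, and compared with a
    single pair of one-sided two-sample KS tests using the standard
    asymptotic p-value.  This mirrors the shuffled-distance description the
    index originates from; its absolute p-values are anti-conservative under
    the dependence above, so it suits comparative use (e.g. onset alignment)
    rather than calibrated thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .events import BinaryRaster
from .session_io import CellMap


@dataclass
class SCIParams:
    n_shuffles: int = 1000
    onset_window: float = 2.5  # s post-onset over which the peak is taken
    baseline_window: float = 4.0  # s pre-onset used for normalization
    scheme: str = "cell_permutation"  # or "distance_pool"
    #: independent null realizations per active-cell count, cycled across
    #: frames; >1 reduces the shared-null variance of tail-rate estimates
    n_null_realizations: int = 1

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.n_null_realizations < 1:
            raise ValueError("n_null_realizations must be >= 1")
        if not (self.onset_window > 0 and self.baseline_window > 0):
            raise ValueError("windows must be positive")
        if self.scheme not in ("cell_permutation", "distance_pool"):
            raise ValueError("scheme must be cell_permutation or distance_pool")


@dataclass
class SCISeries:
    """Signed per-frame index (log10-p units) and active-pair counts."""

    sci: np.ndarray
    n_active_pairs: np.ndarray
    bin_duration: float
    t_start: float

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.sci.size) * self.bin_duration


def active_pair_distances(active_frame: np.ndarray, cell_map: CellMap) -> np.ndarray:
    """Distances (µm) between all unordered pairs of cells active in a frame."""
    idx = np.flatnonzero(np.asarray(active_frame, dtype=bool))
    if idx.size < 2:
        return np.empty(0)
    return pdist(cell_map.centroids[idx])


def _ks_one_sided(obs: np.ndarray, null_sorted: np.ndarray) -> tuple[float, float]:
    """One-sided two-sample KS statistics ``(d_plus, d_minus)``.

    ``d_plus`` is the largest excess of the observed CDF above the null
    (observed values stochastically smaller, i.e. clustered); ``d_minus`` the
    reverse.
    """
    obs = np.sort(np.asarray(obs, dtype=float))
    k = obs.size
    m = null_sorted.size
    f_right = np.searchsorted(null_sorted, obs, side="right") / m
    f_left = np.searchsorted(null_sorted, obs, side="left") / m
    i = np.arange(1, k + 1)
    d_plus = float(np.max(i / k - f_right))
    d_minus = float(np.max(f_left - (i - 1) / k))
    return d_plus, d_minus


def _ks_rows(rows: np.ndarray, null_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-sided KS statistics for many same-size samples."""
    rows = np.sort(rows, axis=1)
    m = null_sorted.size
    k = rows.shape[1]
    f_right = np.searchsorted(null_sorted, rows.ravel(), side="right").reshape(rows.shape) / m
    f_left = np.searchsorted(null_sorted, rows.ravel(), side="left").reshape(rows.shape) / m
    i = np.arange(1, k + 1)
    d_plus = np.max(i / k - f_right, axis=1)
    d_minus = np.max(f_left - (i - 1) / k, axis=1)
    return d_plus, d_minus


def _asymptotic_p(d: float, k: int, m: int) -> float:
    """Standard one-sided two-sample asymptotic KS p-value."""
    n_eff = k * m / (k + m)
    return float(min(1.0, np.exp(-2.0 * n_eff * max(d, 0.0) ** 2)))


def _pooled_distance_null(
    pool: np.ndarray, k: int, n_shuffles: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled null: ``n_shuffles`` draws of ``k`` distances without replacement."""
    n = pool.size
    if k >= n:
        return np.sort(np.tile(pool, n_shuffles))
    keys = rng.random((n_shuffles, n))
    idx = np.argpartition(keys, k, axis=1)[:, :k]
    return np.sort(pool[idx].ravel())


def _signed_from_ps(p_clu: float, p_dis: float, d_plus: float, d_minus: float) -> float:
    if p_clu < p_dis or (p_clu == p_dis and d_plus >= d_minus):
        return float(-np.log10(max(p_clu, 1e-300)))
    return float(np.log10(max(p_dis, 1e-300)))


def frame_sci(
    frame_distances: np.ndarray,
    all_pair_distances: np.ndarray,
    params: SCIParams | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Signed SCI for one frame under the ``distance_pool`` scheme.

    Takes the frame's active-pair distances and the full pairwise-distance
    pool; the null is built by pooled distance resampling (this scheme needs
    only distances, not cell identities).  Returns exactly 0.0 when the frame
    has no active pair.  For the calibrated cell-permutation scheme use
    :class:`SCIComputer` or :func:`sci_series`.
    """
    params = params or SCIParams()
    frame_distances = np.asarray(frame_distances, dtype=float)
    if frame_distances.size == 0:
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.asarray(all_pair_distances, dtype=float)
    null = _pooled_distance_null(pool, frame_distances.size, params.n_shuffles, rng)
    d_plus, d_minus = _ks_one_sided(frame_distances, null)
    p_clu = _asymptotic_p(d_plus, frame_distances.size, null.size)
    p_dis = _asymptotic_p(d_minus, frame_distances.size, null.size)
    return _signed_from_ps(p_clu, p_dis, d_plus, d_minus)


class SCIComputer:
    """Per-frame SCI with null samples cached per active-cell count.

    The null for a frame depends only on how many cells are active, so draws
    are made once per distinct count and reused across frames (mirroring the
    reuse of shuffle offsets in the co-activity null).
    """

    def __init__(
        self,
        cell_map: CellMap,
        params: SCIParams | None = None,
        seed: int | np.random.Generator = 0,
    ) -> None:
        self.params = params or SCIParams()
        self.cell_map = cell_map
        self.dmat = squareform(pdist(cell_map.centroids))
        self.pool = pdist(cell_map.centroids)
        self.rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        self._cache: dict[int, list] = {}
        self._next: dict[int, int] = {}

    def _subset_draws(self, a: int) -> np.ndarray:
        """(n_shuffles, a) random cell subsets without replacement."""
        n = self.cell_map.n_cells
        keys = self.rng.random((self.params.n_shuffles, n))
        return np.argpartition(keys, a - 1, axis=1)[:, :a]

    def _build_null(self, a: int) -> tuple:
        if self.params.scheme == "cell_permutation":
            subs = self._subset_draws(a)
            ii, jj = np.triu_indices(a, k=1)
            draws = self.dmat[subs[:, ii], subs[:, jj]]  # (n_shuffles, k)
            null_sorted = np.sort(draws.ravel())
            d_plus, d_minus = _ks_rows(draws, null_sorted)
            return null_sorted, np.sort(d_plus), np.sort(d_minus)
        k = a * (a - 1) // 2
        null_sorted = _pooled_distance_null(
            self.pool, k, self.params.n_shuffles, self.rng
        )
        return null_sorted, None, None

    def _null_for_count(self, a: int) -> tuple:
        if a not in self._cache:
            self._cache[a] = [
                self._build_null(a) for _ in range(self.params.n_null_realizations)
            ]
            self._next[a] = 0
        entries = self._cache[a]
        i = self._next[a]
        self._next[a] = (i + 1) % len(entries)
        return entries[i]

    def frame(self, active_frame: np.ndarray) -> tuple[float, int]:
        """Signed SCI and active-pair count for one boolean frame."""
        idx = np.flatnonzero(np.asarray(active_frame, dtype=bool))
        a = idx.size
        if a < 2:
            return 0.0, 0
        d = self.dmat[np.ix_(idx, idx)][np.triu_indices(a, k=1)]
        k = d.size
        null_sorted, dp_dist, dm_dist = self._null_for_count(a)
        d_plus, d_minus = _ks_one_sided(d, null_sorted)
        if self.params.scheme == "cell_permutation":
            # conservative Monte Carlo p-value: (1 + #exceedances) / n_shuffles
            n = self.params.n_shuffles
            ge_plus = n - np.searchsorted(dp_dist, d_plus - 1e-12, side="left")
            ge_minus = n - np.searchsorted(dm_dist, d_minus - 1e-12, side="left")
            p_clu = min(1.0, (1.0 + ge_plus) / n)
            p_dis = min(1.0, (1.0 + ge_minus) / n)
        else:
            p_clu = _asymptotic_p(d_plus, k, null_sorted.size)
            p_dis = _asymptotic_p(d_minus, k, null_sorted.size)
        return _signed_from_ps(p_clu, p_dis, d_plus, d_minus), k


def sci_series(
    raster: BinaryRaster,
    cell_map: CellMap,
    params: SCIParams | None = None,
    seed: int = 0,
    smoothed: bool = True,
) -> SCISeries:
    """SCI for every frame of a binary raster.

    The raster should be the forward-smoothed substrate used for co-activity
    (pass ``smoothed=False`` to apply the 1 s forward smoothing here), so
    that "active" means the same thing in both analyses.
    """
    from .coactivity import forward_smooth

    params = params or SCIParams()
    active = raster.active if smoothed else forward_smooth(raster.active)
    comp = SCIComputer(cell_map, params, seed)
    n_bins = active.shape[1]
    sci = np.zeros(n_bins)
    npairs = np.zeros(n_bins, dtype=int)
    for f in range(n_bins):
        sci[f], npairs[f] = comp.frame(active[:, f])
    return SCISeries(
        sci=sci,
        n_active_pairs=npairs,
        bin_duration=raster.bin_duration,
        t_start=raster.t_start,
    )


def exact_permutation_pvalues(
    active_cells: np.ndarray, cell_map: CellMap
) -> tuple[float, float]:
    """Exact permutation p-values for the clustered / dispersed KS statistics.

    Enumerates every equal-size subset of cells, recomputes the one-sided KS
    statistics of the subset's pair distances against the full pair-distance
    pool, and returns the exact tail probabilities (clustered, dispersed).
    Feasible only for small populations; the Monte Carlo cell-permutation
    p-values converge to these as ``n_shuffles`` grows.
    """
    idx = np.flatnonzero(np.asarray(active_cells, dtype=bool))
    n_cells = cell_map.n_cells
    if idx.size < 2:
        raise ValueError("need at least two active cells")
    if comb(n_cells, idx.size) > 2_000_000:
        raise ValueError("population too large for exact enumeration")
    pool = np.sort(pdist(cell_map.centroids))
    d_obs = pdist(cell_map.centroids[idx])
    dp_obs, dm_obs = _ks_one_sided(d_obs, pool)
    ge_plus = 0
    ge_minus = 0
    total = 0
    for subset in combinations(range(n_cells), idx.size):
        d = pdist(cell_map.centroids[list(subset)])
        dp, dm = _ks_one_sided(d, pool)
        ge_plus += dp >= dp_obs - 1e-12
        ge_minus += dm >= dm_obs - 1e-12
        total += 1
    return ge_plus / total, ge_minus / total


def onset_aligned_sci(
    series: SCISeries, onsets: np.ndarray, params: SCIParams | None = None
) -> dict:
    """Average the SCI around movement onsets and normalize to baseline.

    The per-offset mean is divided by the mean SCI over the pre-onset
    baseline window (the rest period the onset definition requires); the
    reported peak is the maximum of the normalized curve within
    ``[0, onset_window]`` seconds post-onset.
    """
    params = params or SCIParams()
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("at least one movement onset is required")
    bd = series.bin_duration
    pre = int(round(params.baseline_window / bd))
    post = int(round(params.onset_window / bd))
    offsets = np.arange(-pre, post + 1) * bd
    vals = np.full((onsets.size, offsets.size), np.nan)
    for oi, onset in enumerate(onsets):
        c = int(round((onset - series.t_start) / bd))
        for ji, j in enumerate(range(c - pre, c + post + 1)):
            if 0 <= j < series.sci.size:
                vals[oi, ji] = series.sci[j]
    mean_curve = np.nanmean(vals, axis=0)
    baseline = np.nanmean(mean_curve[offsets < 0])
    normalized = (
        mean_curve / baseline if baseline != 0 else np.full_like(mean_curve, np.nan)
    )
    post_mask = (offsets >= 0) & (offsets <= params.onset_window)
    peak = (
        float(np.nanmax(normalized[post_mask]))
        if np.isfinite(normalized).any()
        else float("nan")
    )
    return {
        "offsets": offsets,
        "mean": mean_curve,
        "normalized": normalized,
        "baseline": float(baseline),
        "peak": peak,
        "n_onsets": int(onsets.size),
    }
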