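"""Shared fixtures and brute-force oracles.

The oracles are deliberately naive (python loops over definitions) and stay
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from spncoact import synthetic
from spncoact.session_io import CellMap


@pytest.fixture(scope="session")
def tiny_sim():
    """Small full session used by several suites (20 cells, 5 min)."""
    cfg = synthetic.SimConfig(n_cells=20, duration=300.0, seed=1)
    return synthetic.simulate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cell_map(rng):
    return CellMap(centroids=rng.uniform(0, 600, size=(12, 2)), fov=(600.0, 600.0))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_jaccard(a: np.ndarray, b: np.ndarray, frames=None) -> float:
    """Jaccard index by frame-by-frame counting."""
    idx = range(len(a)) if frames is None else frames
    inter = union = 0
    for f in idx:
        if a[f] and b[f]:
            inter += 1
        if a[f] or b[f]:
            union += 1
    return np.nan if union == 0 else inter / union


def brute_forward_smooth(active: np.ndarray, window: int = 5) -> np.ndarray:
    """Forward dilation by scanning each active bin."""
    out = np.array(active, dtype=bool, copy=True)
    n = out.shape[-1]
    for row in np.atleast_2d(out):
        src = row.copy()
        for k in range(n):
            if src[k]:
                row[k : min(n, k + window + 1)] = True
    return out


def brute_detect_events(z, times, threshold=2.5, min_bins=5, bin_duration=0.2):
    """Run-length scanner over the definition of an event."""
    events = []
    active = np.zeros(len(z), dtype=bool)
    k = 0
    n = len(z)
    while k < n:
        if not np.isnan(z[k]) and z[k] >= threshold:
            j = k
            while j < n and not np.isnan(z[j]) and z[j] >= threshold:
                j += 1
            if j - k >= min_bins:
                active[k:j] = True
                peak = k + int(np.argmax(z[k:j]))
                m = k
                while m > 0 and not np.isnan(z[m - 1]) and z[m - 1] < z[m]:
                    m -= 1
                events.append(
                    (0.5 * (times[m] + times[peak]), z[peak], (j - k) * bin_duration)
                )
            k = j
        else:
            k += 1
    return events, active


def brute_sliding_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered median with shrinking edge windows."""
    half = window // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = np.median(x[lo : hi])
    return out


def brute_bin_assign(ts: np.ndarray, t0: float, t_end: float, bd: float, n_bins: int):
    """Half-open binning by scanning each timestamp.

    Includes the 1 ns edge guard of the binning contract (a stamp exactly on
    a bin edge opens that bin).
    """
    out = np.full(len(ts), -1, dtype=int)
    for i, t in enumerate(ts):
        if t < t0:
            continue
        b = int(np.floor((t - t0 + 1e-9) / bd))
        if b < n_bins:
            out[i] = b
    return out


def brute_ks_one_sided(obs, null):
    """One-sided two-sample KS statistics from explicit ECDF evaluation."""
    obs = np.sort(np.asarray(obs, float))
    null = np.sort(np.asarray(null, float))
    k, m = len(obs), len(null)
    d_plus = d_minus = 0.0
    for i, x in enumerate(obs, start=1):
        f_null_right = np.sum(null <= x) / m
        f_null_left = np.sum(null < x) / m
        d_plus = max(d_plus, i / k - f_null_right)
        d_minus = max(d_minus, f_null_left - (i - 1) / k)
    return d_plus, d_minus
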