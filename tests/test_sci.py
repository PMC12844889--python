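"""Spatial coordination index: distances, p-values, signs, onset alignment."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from conftest import brute_ks_one_sided
from spncoact import sci as scimod
from spncoact.events import BinaryRaster
from spncoact.sci import (
    SCIComputer,
    SCIParams,
    active_pair_distances,
    exact_permutation_pvalues,
    frame_sci,
    onset_aligned_sci,
    sci_series,
)
from spncoact.session_io import CellMap


def test_active_pair_distances_cases(small_cell_map):
    none = np.zeros(12, dtype=bool)
    assert active_pair_distances(none, small_cell_map).size == 0
    one = none.copy()
    one[4] = True
    assert active_pair_distances(one, small_cell_map).size == 0
    three = none.copy()
    three[[1, 5, 9]] = True
    d = active_pair_distances(three, small_cell_map)
    assert d.size == 3  # C(3,2)
    pts = small_cell_map.centroids[[1, 5, 9]]
    expect = sorted(
        np.hypot(*(pts[i] - pts[j])) for i in range(3) for j in range(i + 1, 3)
    )
    assert np.allclose(sorted(d), expect)
    coincident = CellMap(centroids=np.zeros((4, 2)), fov=(10, 10))
    assert np.all(active_pair_distances(np.ones(4, bool), coincident) == 0.0)


def test_no_active_pairs_scores_exactly_zero(small_cell_map):
    pool = pdist(small_cell_map.centroids)
    assert frame_sci(np.empty(0), pool, seed=5) == 0.0
    comp = SCIComputer(small_cell_map, seed=5)
    assert comp.frame(np.zeros(12, bool)) == (0.0, 0)
    one = np.zeros(12, bool)
    one[3] = True
    assert comp.frame(one) == (0.0, 0)


def test_ks_statistics_match_ecdf_oracle(rng):
    obs = rng.uniform(0, 100, 15)
    null = rng.uniform(0, 100, 400)
    dp, dm = scimod._ks_one_sided(obs, np.sort(null))
    odp, odm = brute_ks_one_sided(obs, null)
    assert dp == pytest.approx(odp)
    assert dm == pytest.approx(odm)


def _clustered_map(rng, n=40, fov=600.0):
    return CellMap(centroids=rng.uniform(0, fov, (n, 2)), fov=(fov, fov))


@pytest.mark.parametrize("scheme", ["cell_permutation", "distance_pool"])
def test_sign_flips_for_proximal_vs_distal(scheme, rng):
    cm = _clustered_map(rng)
    params = SCIParams(scheme=scheme)
    d2c = np.linalg.norm(cm.centroids - 300.0, axis=1)
    prox = np.zeros(40, bool)
    prox[np.argsort(d2c)[:8]] = True
    distal = np.zeros(40, bool)
    distal[np.argsort(-d2c)[:8]] = True
    comp = SCIComputer(cm, params, seed=3)
    s_prox, k = comp.frame(prox)
    s_dist, _ = comp.frame(distal)
    assert k == 28
    assert s_prox > 0
    assert s_dist < 0


def test_exact_permutation_matches_enumeration_oracle(rng):
    cm = CellMap(centroids=rng.uniform(0, 100, (9, 2)), fov=(100, 100))
    active = np.zeros(9, bool)
    active[[0, 3, 7]] = True
    p_clu, p_dis = exact_permutation_pvalues(active, cm)

    # independent oracle: loop over subsets with the plain ECDF statistics
    from itertools import combinations

    pool = np.sort(pdist(cm.centroids))
    obs = pdist(cm.centroids[[0, 3, 7]])
    dp_obs, dm_obs = brute_ks_one_sided(obs, pool)
    ge_p = ge_m = total = 0
    for sub in combinations(range(9), 3):
        d = pdist(cm.centroids[list(sub)])
        dp, dm = brute_ks_one_sided(d, pool)
        ge_p += dp >= dp_obs - 1e-12
        ge_m += dm >= dm_obs - 1e-12
        total += 1
    assert p_clu == pytest.approx(ge_p / total)
    assert p_dis == pytest.approx(ge_m / total)


def test_monte_carlo_p_converges_to_exact(rng):
    cm = CellMap(centroids=rng.uniform(0, 100, (10, 2)), fov=(100, 100))
    active = np.zeros(10, bool)
    active[[1, 2, 8, 9]] = True
    p_clu_exact, p_dis_exact = exact_permutation_pvalues(active, cm)
    comp = SCIComputer(cm, SCIParams(n_shuffles=4000), seed=0)
    s, k = comp.frame(active)
    p_mc = 10.0 ** (-abs(s))
    p_exact = min(p_clu_exact, p_dis_exact)
    se = np.sqrt(p_exact * (1 - p_exact) / 4000)
    assert abs(p_mc - p_exact) < 4 * se + 2.0 / 4000


def test_sci_series_determinism_and_zero_invariant(rng):
    cm = _clustered_map(rng, n=20)
    active = rng.random((20, 300)) < 0.1
    br = BinaryRaster(active=active, bin_duration=0.2, t_start=0.0)
    params = SCIParams(n_shuffles=200)
    a = sci_series(br, cm, params, seed=9)
    b = sci_series(br, cm, params, seed=9)
    assert np.array_equal(a.sci, b.sci)
    assert np.array_equal(a.n_active_pairs, b.n_active_pairs)
    # sci == 0 exactly when there are no active pairs
    assert np.all((a.sci == 0.0) == (a.n_active_pairs == 0))
    assert np.all(np.isfinite(a.sci))


def test_onset_aligned_constant_series():
    series = scimod.SCISeries(
        sci=np.full(500, 1.7),
        n_active_pairs=np.ones(500, dtype=int),
        bin_duration=0.2,
        t_start=0.0,
    )
    out = onset_aligned_sci(series, onsets=np.array([30.0, 50.0, 70.0]))
    assert np.allclose(out["normalized"], 1.0)
    assert out["peak"] == pytest.approx(1.0)


def test_onset_aligned_single_onset_is_raw_segment(rng):
    vals = rng.normal(1.0, 0.2, size=400)
    series = scimod.SCISeries(
        sci=vals, n_active_pairs=np.ones(400, int), bin_duration=0.2, t_start=0.0
    )
    params = SCIParams(onset_window=2.0, baseline_window=2.0)
    out = onset_aligned_sci(series, onsets=np.array([40.0]), params=params)
    c = 200  # bin of the onset
    seg = vals[c - 10 : c + 11]
    assert np.allclose(out["mean"], seg)


def test_onset_aligned_peak_above_one_for_post_onset_drive():
    # sci elevated for 1 s after each onset
    sci = np.full(1000, 0.5)
    onsets = np.array([40.0, 100.0, 160.0])
    for onset in onsets:
        c = int(onset / 0.2)
        sci[c : c + 5] = 2.5
    series = scimod.SCISeries(
        sci=sci, n_active_pairs=np.ones(1000, int), bin_duration=0.2, t_start=0.0
    )
    out = onset_aligned_sci(series, onsets)
    assert out["peak"] > 1.0
    assert onset_aligned_sci(series, onsets)["baseline"] == pytest.approx(0.5)


def test_onset_aligned_requires_onsets():
    series = scimod.SCISeries(
        sci=np.zeros(10), n_active_pairs=np.zeros(10, int), bin_duration=0.2, t_start=0.0
    )
    with pytest.raises(ValueError):
        onset_aligned_sci(series, onsets=np.array([]))
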