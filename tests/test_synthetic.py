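"""Generator: geometry, locomotion, event trains, rendering, determinism."""

import numpy as np
import pytest

from spncoact import behavior, synthetic
from spncoact.synthetic import MIN_EVENT_SEPARATION, GroundTruth, SimConfig


@pytest.mark.parametrize(
    "kwargs",
    [
        {"fov_width": 0.0},
        {"duration": -1.0},
        {"p_coactivate": 1.5},
        {"ensemble_radius": 0.0},
        {"bout_mean_length": 0.0},
        {"noise_sd": -0.1},
    ],
)
def test_config_rejects_invalid_values(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_cell_map_bounds_membership_and_empty():
    cfg = SimConfig(n_cells=100, fov_width=600, fov_height=600, n_ensembles=2,
                    ensemble_radius=50, seed=1)
    cm, ens = synthetic.generate_cell_map(cfg)
    assert cm.centroids.shape == (100, 2)
    assert np.all(cm.centroids >= 0) and np.all(cm.centroids <= 600)
    # every member lies within the radius of its center (distance recomputation)
    for c in range(100):
        e = ens.membership[c]
        if e >= 0:
            d = np.hypot(*(cm.centroids[c] - ens.centers[e]))
            assert d <= 50.0 + 1e-9
    empty, _ = synthetic.generate_cell_map(SimConfig(n_cells=0, seed=1))
    assert empty.n_cells == 0


def test_locomotion_move_speed_and_rest_jitter():
    cfg = SimConfig(mean_move_speed=4.0, duration=600.0, seed=7)
    tracking, loco = synthetic.simulate_locomotion(cfg)
    v = behavior.compute_velocity(tracking)
    # map tracking frames to epochs
    move_mask = np.zeros(v.size, dtype=bool)
    rest_mask = np.zeros(v.size, dtype=bool)
    for s, e, label in loco.epochs:
        sel = (tracking.timestamps >= s) & (tracking.timestamps < e)
        (move_mask if label == "move" else rest_mask)[sel] = True
    # skip the frame straddling each epoch boundary (velocity mixes epochs)
    trans = np.r_[False, np.abs(np.diff(move_mask.astype(int))) > 0]
    mean_move = v[move_mask & ~trans].mean()
    assert abs(mean_move - 4.0) / 4.0 < 0.2
    frac_slow_rest = np.mean(v[rest_mask & ~trans] < 0.5)
    assert frac_slow_rest > 0.95


def test_locomotion_single_move_epoch_limit():
    cfg = SimConfig(bout_mean_length=1e7, rest_mean_length=1e-3, duration=300.0, seed=3)
    _, loco = synthetic.simulate_locomotion(cfg)
    assert loco.state_sequence.mean() > 0.99


def test_homogeneous_rate_matches_renewal_expectation():
    # slope 0, no ensembles: independent trains; the enforced minimum
    # separation makes the realized rate 1/(tau + 1/lambda)
    cfg = SimConfig(n_cells=40, duration=1200.0, base_rate=0.01,
                    rate_velocity_slope=0.0, p_coactivate=0.0, seed=5)
    rng = np.random.default_rng(cfg.seed)
    cm, ens = synthetic.generate_cell_map(cfg, rng)
    _, loco = synthetic.simulate_locomotion(cfg, rng)
    gt = synthetic.simulate_event_trains(cfg, cm, ens, loco, rng)
    n_events = sum(len(t) for t in gt.event_times)
    expected_rate = 1.0 / (MIN_EVENT_SEPARATION + 1.0 / cfg.base_rate)
    expected_n = expected_rate * cfg.duration * cfg.n_cells
    se = np.sqrt(expected_n)
    assert abs(n_events - expected_n) < 3 * se


def test_forced_coincidence_with_p_one():
    cfg = SimConfig(n_cells=30, fov_width=300, fov_height=300, duration=300.0,
                    n_ensembles=1, ensemble_radius=150, p_coactivate=1.0,
                    base_rate=1e-9, rate_velocity_slope=0.0,
                    rest_shared_drive=0.1, move_shared_drive=0.1, seed=2)
    rng = np.random.default_rng(cfg.seed)
    cm, ens = synthetic.generate_cell_map(cfg, rng)
    _, loco = synthetic.simulate_locomotion(cfg, rng)
    gt = synthetic.simulate_event_trains(cfg, cm, ens, loco, rng)
    members = np.flatnonzero(gt.ensemble_membership == 0)
    assert members.size >= 2
    ref = gt.event_times[members[0]]
    assert ref.size > 0
    for c in members[1:]:
        assert np.array_equal(gt.event_times[c], ref)


def test_velocity_coupled_rates_by_quartile():
    cfg = SimConfig(n_cells=40, duration=1200.0, base_rate=0.01,
                    rate_velocity_slope=0.02, p_coactivate=0.0, seed=4)
    rng = np.random.default_rng(cfg.seed)
    cm, ens = synthetic.generate_cell_map(cfg, rng)
    _, loco = synthetic.simulate_locomotion(cfg, rng)
    gt = synthetic.simulate_event_trains(cfg, cm, ens, loco, rng)
    v = loco.true_velocity
    q1, q3 = np.quantile(v, [0.25, 0.75])
    lo_frames = v <= q1
    hi_frames = v >= q3
    lo = hi = 0
    for ts in gt.event_times:
        frames = np.floor(np.asarray(ts) * cfg.acq_rate).astype(int)
        frames = np.clip(frames, 0, v.size - 1)
        lo += lo_frames[frames].sum()
        hi += hi_frames[frames].sum()
    lo_rate = lo / lo_frames.sum()
    hi_rate = hi / hi_frames.sum()
    assert hi_rate > lo_rate


def test_render_null_and_noise_properties():
    cfg = SimConfig(n_cells=3, duration=60.0, noise_sd=0.0, seed=9)
    gt = GroundTruth(
        event_times=[np.empty(0)] * 3,
        ensemble_membership=np.full(3, -1),
        state_sequence=np.zeros(1200, dtype=bool),
        true_velocity=np.zeros(1200),
    )
    sess = synthetic.render_fluorescence(gt, cfg)
    assert np.all(sess.traces == 0.0)

    cfg_noise = SimConfig(n_cells=3, duration=120.0, noise_sd=0.1, seed=9)
    gt2 = GroundTruth(
        event_times=[np.empty(0)] * 3,
        ensemble_membership=np.full(3, -1),
        state_sequence=np.zeros(2400, dtype=bool),
        true_velocity=np.zeros(2400),
    )
    sess2 = synthetic.render_fluorescence(gt2, cfg_noise)
    assert abs(sess2.traces.std() - 0.1) / 0.1 < 0.1


def test_render_single_event_peak_location():
    cfg = SimConfig(n_cells=1, duration=30.0, noise_sd=0.0, seed=9)
    gt = GroundTruth(
        event_times=[np.array([10.0])],
        ensemble_membership=np.array([-1]),
        state_sequence=np.zeros(600, dtype=bool),
        true_velocity=np.zeros(600),
    )
    sess = synthetic.render_fluorescence(gt, cfg)
    t_max = sess.timestamps[np.argmax(sess.traces[0])]
    assert 10.0 <= t_max <= 10.0 + 5 * cfg.kernel_decay


def test_render_onset_count_matches_events():
    # sparse constructed train: rendered transients = one run per event
    cfg = SimConfig(n_cells=1, duration=60.0, noise_sd=0.0, seed=9)
    times = np.array([5.0, 15.0, 30.0, 48.0])
    gt = GroundTruth(
        event_times=[times],
        ensemble_membership=np.array([-1]),
        state_sequence=np.zeros(1200, dtype=bool),
        true_velocity=np.zeros(1200),
    )
    sess = synthetic.render_fluorescence(gt, cfg)
    above = sess.traces[0] > 0.3
    n_runs = int(np.sum(np.diff(np.r_[False, above].astype(int)) == 1))
    assert n_runs == times.size


def test_seed_determinism_bitwise():
    cfg = SimConfig(n_cells=15, duration=120.0, seed=42)
    a = synthetic.simulate_session(cfg)
    b = synthetic.simulate_session(cfg)
    assert np.array_equal(a.session.traces, b.session.traces)
    assert np.array_equal(a.tracking.x_px, b.tracking.x_px)
    assert all(
        np.array_equal(x, y)
        for x, y in zip(a.ground_truth.event_times, b.ground_truth.event_times)
    )


def test_ground_truth_invariants(tiny_sim):
    gt = tiny_sim.ground_truth
    dur = tiny_sim.config.duration
    assert gt.ensemble_membership.size == tiny_sim.config.n_cells
    for ts in gt.event_times:
        assert np.all(np.diff(ts) >= MIN_EVENT_SEPARATION - 1e-9)
        assert np.all((ts >= 0) & (ts < dur))


def test_clustering_by_construction():
    # within-ensemble coincidence (+-1 s) exceeds cross-ensemble, by brute count
    cfg = SimConfig(n_cells=40, fov_width=300, fov_height=300, duration=600.0,
                    n_ensembles=2, ensemble_radius=100, p_coactivate=0.5,
                    base_rate=0.01, rate_velocity_slope=0.0,
                    rest_shared_drive=0.3, move_shared_drive=0.3, seed=6)
    rng = np.random.default_rng(cfg.seed)
    cm, ens = synthetic.generate_cell_map(cfg, rng)
    _, loco = synthetic.simulate_locomotion(cfg, rng)
    gt = synthetic.simulate_event_trains(cfg, cm, ens, loco, rng)

    def coincidences(a, b):
        return sum(1 for t in gt.event_times[a] if np.any(np.abs(gt.event_times[b] - t) <= 1.0))

    within = []
    cross = []
    n = cfg.n_cells
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = gt.ensemble_membership[i], gt.ensemble_membership[j]
            if mi < 0 or mj < 0:
                continue
            (within if mi == mj else cross).append(coincidences(i, j))
    assert np.mean(within) > np.mean(cross)
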