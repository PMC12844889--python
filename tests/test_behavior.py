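"""Velocity computation, epoch classification, bout segmentation, onsets."""

import numpy as np
import pytest

from conftest import brute_sliding_median
from spncoact import behavior
from spncoact.behavior import (
    LocomotionTrace,
    OnsetParams,
    classify_epochs,
    compute_velocity,
    detect_onsets,
    filter_velocity,
    median_filter_centered,
    onset_filtered_velocity,
)
from spncoact.session_io import FluorescenceSession, TrackingData, align_streams


def _tracking(x_cm, y_cm, rate=30.0, cm_per_px=0.1):
    n = len(x_cm)
    return TrackingData(
        frame=np.arange(n),
        timestamps=np.arange(n) / rate,
        x_px=np.asarray(x_cm) / cm_per_px,
        y_px=np.asarray(y_cm) / cm_per_px,
        cm_per_px=cm_per_px,
    )


def _loco(v5, bd=0.2):
    v5 = np.asarray(v5, dtype=float)
    return LocomotionTrace(
        velocity=v5,
        raw_velocity=v5,
        valid=np.ones(v5.size, dtype=bool),
        bin_duration=bd,
        t_start=0.0,
    )


def test_velocity_stationary_and_straight_line():
    n = 300
    assert np.all(compute_velocity(_tracking(np.zeros(n), np.zeros(n))) == 0.0)
    # 1 px/frame at 30 fps with 0.1 cm/px -> 3 cm/s
    trk = _tracking(np.arange(n) * 0.1, np.zeros(n))
    v = compute_velocity(trk)
    assert v[0] == 0.0
    assert np.allclose(v[1:], 3.0)


def test_velocity_circular_path_closed_form():
    rate, T, r = 30.0, 8.0, 10.0  # cm
    t = np.arange(int(rate * 3 * T)) / rate
    x = r * np.cos(2 * np.pi * t / T) + 30
    y = r * np.sin(2 * np.pi * t / T) + 30
    v = compute_velocity(_tracking(x, y))
    expected = 2 * np.pi * r / T
    assert abs(np.median(v[1:]) - expected) / expected < 0.01


def test_median_filter_spike_removal_and_oracle():
    x = np.full(90, 2.0)
    x[45] = 50.0
    assert np.all(median_filter_centered(x, 31) == 2.0)
    rng = np.random.default_rng(5)
    y = rng.normal(size=200)
    assert np.allclose(median_filter_centered(y, 31), brute_sliding_median(y, 31))


def test_filter_velocity_constant_preserved():
    n = 900  # 30 s at 30 fps
    trk = _tracking(np.arange(n) * 0.1, np.zeros(n))
    sess = FluorescenceSession(
        traces=np.arange(600, dtype=float)[None, :],
        timestamps=np.arange(600) / 20.0,
        acq_rate=20.0,
        cell_ids=["c0"],
    )
    grid = align_streams(sess, trk)
    loco = filter_velocity(compute_velocity(trk), trk, grid)
    assert np.nanmax(np.abs(loco.velocity[1:] - 3.0)) < 1e-9


def test_classify_epochs_all_rest():
    ep = classify_epochs(_loco(np.zeros(100)))
    assert ep.n_bouts == 0
    assert len(ep.rest_intervals) == 1
    assert ep.rest_time == pytest.approx(20.0)


def test_classify_epochs_bout_count_matches_run_oracle():
    rng = np.random.default_rng(11)
    v = rng.choice([0.0, 1.0], size=500)
    ep = classify_epochs(_loco(v))
    runs = int(np.sum(np.diff(np.r_[0, (v > 0.5).astype(int)]) == 1))
    assert ep.n_bouts == runs


def test_boundary_velocity_is_rest():
    ep = classify_epochs(_loco(np.full(10, 0.5)))
    assert ep.n_bouts == 0
    assert ep.fraction_rest == 1.0


def test_epoch_partition_is_exact():
    rng = np.random.default_rng(13)
    v = np.abs(rng.normal(0.5, 0.6, size=400))
    loco = _loco(v)
    loco.valid[50:70] = False
    ep = classify_epochs(loco)
    assert ep.rest_time + ep.move_time == pytest.approx(loco.valid.sum() * 0.2)


def _onset_scenario(rate=30.0):
    """10 s rest | 6 s at 5 cm/s | 10 s rest | 4 s in-place dither |
    6 s rest | 5 s at 4 cm/s | 3 s rest | 3 s at 5 cm/s.

    Onsets expected at t=10 and t=36 only: the dither fails the 1 cm
    displacement rule and the final run has only 3 s of preceding rest.
    """
    dt = 1.0 / rate
    segs = []
    x = y = 0.0

    def hold(dur):
        nonlocal segs
        segs += [(0.0, 0.0)] * int(dur * rate)

    def run(dur, speed):
        nonlocal segs
        segs += [(speed * dt, 0.0)] * int(dur * rate)

    def dither(dur, amp=0.3):
        nonlocal segs
        for i in range(int(dur * rate)):
            segs.append((amp if i % 2 == 0 else -amp, 0.0))

    hold(10.0)
    run(6.0, 5.0)
    hold(10.0)
    dither(4.0)
    hold(6.0)
    run(5.0, 4.0)
    hold(3.0)
    run(3.0, 5.0)
    steps = np.array(segs)
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return _tracking(pos[:, 0], pos[:, 1], rate=rate), (10.0, 36.0)


def test_onset_detector_exact_onsets():
    trk, expected = _onset_scenario()
    onsets = detect_onsets(trk)
    assert len(onsets) == 2
    assert abs(onsets[0] - expected[0]) <= 0.2
    assert abs(onsets[1] - expected[1]) <= 0.2


def test_dither_in_place_is_suppressed():
    # fast frame-to-frame motion that never travels 1 cm in any 1 s window
    n = 600
    x = np.where(np.arange(n) % 2 == 0, 0.0, 0.3)
    trk = _tracking(x, np.zeros(n))
    assert np.all(compute_velocity(trk)[1:] > 0.5)  # raw speed is high
    assert np.all(onset_filtered_velocity(trk) <= 0.5)
    assert len(detect_onsets(trk)) == 0


def test_movement_without_pre_rest_is_not_onset():
    rate = 30.0
    dt = 1 / rate
    # movement starts at t = 2 s: less than the 4 s of required rest
    steps = [(0.0, 0.0)] * int(2 * rate) + [(5 * dt, 0.0)] * int(8 * rate)
    pos = np.vstack([[0.0, 0.0], np.cumsum(np.array(steps), axis=0)])
    trk = _tracking(pos[:, 0], pos[:, 1], rate=rate)
    assert len(detect_onsets(trk)) == 0


def test_translation_invariance():
    trk, _ = _onset_scenario()
    shifted = TrackingData(
        frame=trk.frame,
        timestamps=trk.timestamps,
        x_px=trk.x_px + 1234.5,
        y_px=trk.y_px - 77.0,
        cm_per_px=trk.cm_per_px,
    )
    assert np.allclose(compute_velocity(trk), compute_velocity(shifted))
    assert np.allclose(detect_onsets(trk), detect_onsets(shifted))


def test_short_trace_warns_and_returns_empty():
    trk = _tracking(np.zeros(60), np.zeros(60))  # 2 s
    with pytest.warns(UserWarning):
        onsets = detect_onsets(trk)
    assert onsets.size == 0
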