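"""Ground-truth-annotated synthetic miniscope sessions.

The generator emulates the statistical structure the analysis chain assumes
in real one-photon recordings of striatal projection neurons:

- cells placed uniformly in the field of view, with a configurable number of
  spatial ensembles (cells within ``ensemble_radius`` of an ensemble center);
- alternating rest/movement epochs with exponential lengths, near-zero
  velocity at rest and gamma-distributed bout speeds during movement,
  emitted both as a 30 frames/s pixel-coordinate tracking stream and as a
  ground-truth velocity at the miniscope rate;
- per-cell event trains with instantaneous rate
  ``base_rate + rate_velocity_slope * velocity``, plus ensemble events (a
  homogeneous process per ensemble whose rate depends on behavioral state)
  at which each member cell fires with probability ``p_coactivate`` at
  exactly the shared time;
- GCaMP6f-like fluorescence: each event renders as a compound burst
  transient (several difference-of-exponentials kernels spread over
  ~1.0-1.4 s, peak-normalized to a lognormal amplitude) with additive
  Gaussian noise.  A calcium "event" stands in for a burst of action
  potentials, so the compound transient — not a single-spike kernel — is the
  waveform the threshold detector is meant to find.

A fixed seed gives bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
import json

import numpy as np

from .session_io import CellMap, FluorescenceSession, TrackingData, save_session

#: events closer than this per cell are merged (transients are not separable)
MIN_EVENT_SEPARATION = 1.2  # s

#: lognormal sigma of the per-event amplitude jitter
AMPLITUDE_SIGMA = 0.25

#: half-normal scale of the rest velocity jitter, cm/s
REST_JITTER = 0.1

#: burst-transient plateau duration range, s
BURST_DURATION = (1.0, 1.4)
BURST_KERNELS = 7


@dataclass
class SimConfig:
    """Synthetic session parameters.

    Rates are events/s, lengths seconds, distances µm, speeds cm/s.
    ``rest_shared_drive`` / ``move_shared_drive`` are the state-dependent
    ensemble event rates (events/s per ensemble).
    """

    n_cells: int = 60
    fov_width: float = 600.0
    fov_height: float = 600.0
    duration: float = 1200.0
    acq_rate: float = 20.0
    n_ensembles: int = 3
    ensemble_radius: float = 100.0
    p_coactivate: float = 0.3
    base_rate: float = 0.01
    rate_velocity_slope: float = 0.0075
    rest_shared_drive: float = 0.08
    move_shared_drive: float = 0.02
    bout_mean_length: float = 7.0
    rest_mean_length: float = 6.0
    mean_move_speed: float = 4.0
    kernel_rise: float = 0.05
    kernel_decay: float = 0.4
    noise_sd: float = 0.08
    tracking_rate: float = 30.0
    cm_per_px: float = 0.1
    arena_cm: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        for name in ("fov_width", "fov_height", "duration", "acq_rate",
                     "ensemble_radius", "base_rate", "bout_mean_length",
                     "rest_mean_length", "mean_move_speed", "kernel_rise",
                     "kernel_decay", "tracking_rate", "cm_per_px", "arena_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("rate_velocity_slope", "rest_shared_drive",
                     "move_shared_drive", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.p_coactivate <= 1.0:
            raise ValueError("p_coactivate must be a probability")
        if self.n_ensembles < 0:
            raise ValueError("n_ensembles must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class EnsembleMap:
    centers: np.ndarray  # (n_ensembles, 2) µm
    membership: np.ndarray  # per-cell ensemble index, -1 = none


@dataclass
class LocomotionGroundTruth:
    epochs: list[tuple[float, float, str]]  # (start, end, 'rest'|'move')
    state_sequence: np.ndarray  # per acq frame, True = move
    true_velocity: np.ndarray  # per acq frame, cm/s (bout speed; 0 at rest)


@dataclass
class GroundTruth:
    event_times: list[np.ndarray]  # per cell, sorted, seconds
    ensemble_membership: np.ndarray
    state_sequence: np.ndarray
    true_velocity: np.ndarray


@dataclass
class SimulatedSession:
    config: SimConfig
    session: FluorescenceSession
    cell_map: CellMap
    ensembles: EnsembleMap
    tracking: TrackingData
    ground_truth: GroundTruth
    loco_truth: LocomotionGroundTruth = field(repr=False, default=None)


def generate_cell_map(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CellMap, EnsembleMap]:
    """Place cell centroids uniformly in the field and assign ensembles.

    Ensemble centers are uniform in the field; a cell belongs to the nearest
    center within ``ensemble_radius`` (or to none).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    w, h = cfg.fov_width, cfg.fov_height
    centroids = rng.uniform([0, 0], [w, h], size=(cfg.n_cells, 2))
    # centers inset by the radius so each ensemble fits inside the field
    r = cfg.ensemble_radius
    lo = [min(r, w / 2), min(r, h / 2)]
    hi = [max(w - r, w / 2), max(h - r, h / 2)]
    centers = rng.uniform(lo, hi, size=(cfg.n_ensembles, 2))
    membership = np.full(cfg.n_cells, -1, dtype=int)
    if cfg.n_ensembles and cfg.n_cells:
        d = np.linalg.norm(centroids[:, None, :] - centers[None, :, :], axis=2)
        nearest = np.argmin(d, axis=1)
        within = d[np.arange(cfg.n_cells), nearest] <= cfg.ensemble_radius
        membership[within] = nearest[within]
    cell_map = CellMap(centroids=centroids, fov=(w, h))
    return cell_map, EnsembleMap(centers=centers, membership=membership)


def _draw_epochs(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float, str]]:
    epochs = []
    t = 0.0
    move = bool(rng.integers(0, 2))
    while t < cfg.duration:
        mean = cfg.bout_mean_length if move else cfg.rest_mean_length
        end = min(t + rng.exponential(mean), cfg.duration)
        epochs.append((t, end, "move" if move else "rest"))
        t = end
        move = not move
    return epochs


def simulate_locomotion(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[TrackingData, LocomotionGroundTruth]:
    """Alternating rest/move epochs rendered as a pixel tracking stream.

    Velocity is near zero (half-normal jitter) at rest and follows a per-bout
    gamma speed (floored at 1 cm/s so bouts stay above the 0.5 cm/s
    threshold) during movement.  The centroid performs a heading random walk
    reflected at the arena walls, emitted at ``tracking_rate`` in pixels;
    ground truth (state and bout speed) is sampled at the miniscope rate.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    epochs = _draw_epochs(cfg, rng)
    starts = np.array([e[0] for e in epochs])
    is_move = np.array([e[2] == "move" for e in epochs])
    bout_speed = np.where(
        is_move,
        np.maximum(1.0, rng.gamma(4.0, cfg.mean_move_speed / 4.0, size=len(epochs))),
        0.0,
    )

    def _epoch_of(ts: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(starts, ts, side="right") - 1, 0, len(epochs) - 1)

    # tracking stream at tracking_rate
    n_trk = int(round(cfg.duration * cfg.tracking_rate))
    tts = np.arange(n_trk) / cfg.tracking_rate
    ep = _epoch_of(tts)
    speed = np.where(
        is_move[ep],
        np.clip(bout_speed[ep] * (1.0 + 0.05 * rng.normal(size=n_trk)), 0.6, None),
        np.abs(rng.normal(0.0, REST_JITTER, size=n_trk)),
    )
    theta = np.cumsum(rng.normal(0.0, 0.3, size=n_trk))
    dt = 1.0 / cfg.tracking_rate
    x = np.empty(n_trk)
    y = np.empty(n_trk)
    cx, cy = cfg.arena_cm / 2.0, cfg.arena_cm / 2.0
    for i in range(n_trk):
        x[i], y[i] = cx, cy
        step = speed[i] * dt
        cx += step * np.cos(theta[i])
        cy += step * np.sin(theta[i])
        if cx < 0:
            cx = -cx
        elif cx > cfg.arena_cm:
            cx = 2 * cfg.arena_cm - cx
        if cy < 0:
            cy = -cy
        elif cy > cfg.arena_cm:
            cy = 2 * cfg.arena_cm - cy
    tracking = TrackingData(
        frame=np.arange(n_trk),
        timestamps=tts,
        x_px=x / cfg.cm_per_px,
        y_px=y / cfg.cm_per_px,
        cm_per_px=cfg.cm_per_px,
    )

    # ground truth at acquisition rate
    n_acq = int(round(cfg.duration * cfg.acq_rate))
    ats = np.arange(n_acq) / cfg.acq_rate
    ep_a = _epoch_of(ats)
    state = is_move[ep_a]
    true_v = np.where(state, bout_speed[ep_a], 0.0)
    return tracking, LocomotionGroundTruth(
        epochs=epochs, state_sequence=state, true_velocity=true_v
    )


def _thin_events(
    rate_per_frame: np.ndarray, acq_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous event process by per-frame thinning."""
    dt = 1.0 / acq_rate
    hits = np.flatnonzero(rng.random(rate_per_frame.size) < rate_per_frame * dt)
    return hits / acq_rate + rng.uniform(0.0, dt, size=hits.size)


def _enforce_separation(times: np.ndarray, min_sep: float) -> np.ndarray:
    times = np.sort(times)
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= min_sep:
            keep.append(t)
            last = t
    return np.asarray(keep)


def simulate_event_trains(
    cfg: SimConfig,
    cell_map: CellMap,
    ensembles: EnsembleMap,
    loco: LocomotionGroundTruth,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Per-cell event trains with velocity-coupled rates and ensemble events.

    Independent component: rate ``base_rate + rate_velocity_slope * v(t)``.
    Ensemble component: each ensemble emits events as a state-modulated
    process (``rest_shared_drive`` at rest, ``move_shared_drive`` during
    movement, events/s); at each ensemble event every member cell fires with
    probability ``p_coactivate`` at exactly the shared time.  Events closer
    than ``MIN_EVENT_SEPARATION`` per cell are merged (first kept).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    rate = cfg.base_rate + cfg.rate_velocity_slope * loco.true_velocity
    per_cell = [
        list(_thin_events(rate, cfg.acq_rate, rng)) for _ in range(cfg.n_cells)
    ]
    for e in range(cfg.n_ensembles):
        ens_rate = np.where(
            loco.state_sequence, cfg.move_shared_drive, cfg.rest_shared_drive
        )
        ens_times = _thin_events(ens_rate, cfg.acq_rate, rng)
        members = np.flatnonzero(ensembles.membership == e)
        for t in ens_times:
            fires = members[rng.random(members.size) < cfg.p_coactivate]
            for c in fires:
                per_cell[c].append(t)
    event_times = [
        _enforce_separation(np.asarray(ts), MIN_EVENT_SEPARATION) for ts in per_cell
    ]
    return GroundTruth(
        event_times=event_times,
        ensemble_membership=ensembles.membership.copy(),
        state_sequence=loco.state_sequence.copy(),
        true_velocity=loco.true_velocity.copy(),
    )


def _kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    return out / peak


def render_fluorescence(
    gt: GroundTruth, cfg: SimConfig, rng: np.random.Generator | None = None
) -> FluorescenceSession:
    """Render event trains into noisy fluorescence traces at the miniscope rate.

    Each event becomes a compound burst transient: ``BURST_KERNELS``
    difference-of-exponentials kernels evenly spread over a plateau duration
    drawn from ``BURST_DURATION``, peak-normalized to a lognormal amplitude
    (sigma ``AMPLITUDE_SIGMA``), plus white Gaussian noise of SD ``noise_sd``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.acq_rate))
    t = np.arange(n) / cfg.acq_rate
    traces = np.zeros((cfg.n_cells, n))
    tail = 6.0 * cfg.kernel_decay
    for i, times in enumerate(gt.event_times):
        for ev in np.asarray(times, dtype=float):
            if not 0.0 <= ev < cfg.duration:
                raise ValueError("event time outside session duration")
            d = rng.uniform(*BURST_DURATION)
            amp = rng.lognormal(0.0, AMPLITUDE_SIGMA)
            i0 = int(np.ceil(ev * cfg.acq_rate))
            i1 = min(n, int(np.floor((ev + d + tail) * cfg.acq_rate)) + 1)
            if i0 >= i1:
                continue
            tt = t[i0:i1] - ev
            subs = np.linspace(0.0, d, BURST_KERNELS)
            w = _kernel(tt[:, None] - subs[None, :], cfg.kernel_rise, cfg.kernel_decay).sum(axis=1)
            peak = w.max()
            if peak > 0:
                traces[i, i0:i1] += w * (amp / peak)
    if cfg.noise_sd > 0:
        traces += rng.normal(0.0, cfg.noise_sd, size=traces.shape)
    cell_ids = [f"cell_{i:04d}" for i in range(cfg.n_cells)]
    return FluorescenceSession(
        traces=traces, timestamps=t, acq_rate=cfg.acq_rate, cell_ids=cell_ids
    )


def simulate_session(cfg: SimConfig) -> SimulatedSession:
    """Run the full generator pipeline deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    cell_map, ensembles = generate_cell_map(cfg, rng)
    tracking, loco = simulate_locomotion(cfg, rng)
    gt = simulate_event_trains(cfg, cell_map, ensembles, loco, rng)
    session = render_fluorescence(gt, cfg, rng)
    cell_map.cell_ids = list(session.cell_ids)
    return SimulatedSession(
        config=cfg,
        session=session,
        cell_map=cell_map,
        ensembles=ensembles,
        tracking=tracking,
        ground_truth=gt,
        loco_truth=loco,
    )


def write_session(sim: SimulatedSession, outdir: str | Path) -> Path:
    """Write the session CSVs plus ground-truth JSON and the config."""
    outdir = Path(outdir)
    save_session(outdir, sim.session, sim.cell_map, sim.tracking)
    gt = sim.ground_truth
    payload = {
        "event_times": [list(map(float, ts)) for ts in gt.event_times],
        "ensemble_membership": gt.ensemble_membership.tolist(),
        "state_sequence": gt.state_sequence.astype(int).tolist(),
        "true_velocity": gt.true_velocity.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload))
    try:
        import yaml

        (outdir / "sim_config.yaml").write_text(yaml.safe_dump(sim.config.to_dict()))
    except ImportError:  # pragma: no cover
        (outdir / "sim_config.json").write_text(json.dumps(sim.config.to_dict()))
    return outdir
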