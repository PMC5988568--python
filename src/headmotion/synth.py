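"""Synthetic head trajectories, emulated IMU streams and spike trains.

Everything downstream of the sensor can be validated by parameter recovery:
this module generates ground-truth Euler-angle trajectories with the
statistical structure the analyses assume (Gaussian per-event angular
displacements with axis-specific spreads, weak yaw-roll coupling, optional
Donders-type constraints), inverts the attitude kinematics to produce the
corresponding gyroscope/accelerometer/magnetometer streams, and emits spike
trains of displacement-tuned bursting neurons, AHV-rate-modulated neurons,
azimuth-modulated neurons and untuned Poisson cells.

All generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from headmotion import donders
from headmotion.ahrs import dcm_update as ahrs_dcm_update
from headmotion.ahrs import renormalize as ahrs_renormalize
from headmotion.ahrs import rotation_matrix_from_euler

# Per-axis SDs (deg) of per-event angular displacement emulating foraging
# mice: yaw 22.7, pitch 21.4, roll 18.3.  Yaw-roll coupling -0.102 deg/deg
# reproduces the weak preference for clockwise-yaw/counter-clockwise-roll
# conjunction; yaw x pitch and pitch x roll are independent.
DEFAULT_DISPLACEMENT_SIGMA = (22.7, 21.4, 18.3)
DEFAULT_YAW_ROLL_COUPLING = -0.102


@dataclass
class TrajectoryModel:
    """Parameters of a simulated head trajectory.

    ``kind`` is one of ``unconstrained`` (hold / smooth-displacement-event /
    hold, per-event extents Gaussian per axis), ``listing`` (zero torsion:
    quaternions confined to the qT = 0 plane), ``fick`` / ``helmholtz``
    (nested-gimbal rotations with zero gimbal torsion) or ``rotation_table``
    (constant-velocity yaw, the bench validation condition).
    """

    kind: str = "unconstrained"
    duration: float = 300.0
    dt: float = 0.02
    event_rate: float = 1.0  # movement events per second (~300 per 5-min trial)
    displacement_sigma: tuple[float, float, float] = DEFAULT_DISPLACEMENT_SIGMA
    yaw_roll_coupling: float = DEFAULT_YAW_ROLL_COUPLING
    movement_duration_range: tuple[float, float] = (0.1, 0.3)
    table_speed: float = 80.0  # deg/s, rotation_table only
    gimbal_amplitude: float = 40.0  # deg, fick/helmholtz/listing angle range
    seed: int | None = None


@dataclass
class NeuronModel:
    """Parameters of a simulated neuron.

    ``displacement_tuned`` cells emit a burst (>= 3 spikes at ``burst_rate``)
    starting ``lead_time`` before the onset of motion events whose per-axis
    extents fall within a window around ``preferred_vector`` (only axes with a
    nonzero preferred component are constrained; the window half-width is
    ``tuning_halfwidth_factor`` times the preferred magnitude).  ``ahv_tuned``
    cells are inhomogeneous Poisson with a skewed-Gaussian rate-velocity
    curve; ``azimuth_tuned`` cells have a von-Mises-shaped rate over yaw
    heading; ``untuned_poisson`` cells are homogeneous Poisson.
    """

    kind: str = "displacement_tuned"
    preferred_vector: tuple[float, float, float] = (15.0, 0.0, 0.0)
    lead_time: float = 0.08
    burst_rate: float = 70.0
    reliability: float = 0.8
    tuning_halfwidth_factor: float = 2.0 / 3.0
    baseline_rate: float = 1.0
    ahv_axis: str = "yaw"
    ahv_params: tuple[float, float, float, float] = (7000.0, 150.0, 100.0, 2.0)
    azimuth_params: tuple[float, float, float] = (0.0, 4.0, 20.0)  # pref deg, kappa, peak Hz
    seed: int | None = None


def _raised_cosine_displacement(n: int) -> np.ndarray:
    """Unit displacement profile with raised-cosine velocity (zero at ends)."""
    tau = np.linspace(0.0, 1.0, n + 1)[1:]
    return tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)


def _event_process(
    model: TrajectoryModel,
    rng: np.random.Generator,
    n_axes: int,
    sigmas,
    reversion=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hold / move / hold piecewise trajectory on ``n_axes`` angle channels.

    ``reversion`` (per axis, 0..1) pulls each event partly back toward the
    level position so that an axis stays stationary around zero (a head does
    not somersault); the injected noise is rescaled so the stationary
    *per-event extent* SD still equals the requested sigma exactly.
    """
    if reversion is None:
        reversion = np.zeros(n_axes)
    reversion = np.asarray(reversion, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    noise_sd = sigmas * np.sqrt((2.0 - reversion) / 2.0)
    n = int(round(model.duration / model.dt))
    angles = np.zeros((n, n_axes))
    mean_move = float(np.mean(model.movement_duration_range))
    mean_hold = max(1.0 / model.event_rate - mean_move, 0.05)
    events = []
    t_bin = int(round(rng.exponential(mean_hold) / model.dt))
    while t_bin < n - 1:
        dur = rng.uniform(*model.movement_duration_range)
        n_move = max(int(round(dur / model.dt)), 2)
        end = min(t_bin + n_move, n - 1)
        n_move = end - t_bin
        if n_move < 2:
            break
        extents = -reversion * angles[t_bin] + rng.normal(0.0, 1.0, n_axes) * noise_sd
        profile = _raised_cosine_displacement(n_move)
        for ax in range(n_axes):
            angles[t_bin + 1 : end + 1, ax] = angles[t_bin, ax] + extents[ax] * profile
            angles[end + 1 :, ax] = angles[end, ax]
        events.append(
            {
                "onset_t": t_bin * model.dt,
                "offset_t": end * model.dt,
                **{f"extent_{ax}": extents[ax] for ax in range(n_axes)},
            }
        )
        t_bin = end + int(round(rng.exponential(mean_hold) / model.dt)) + 1
    return angles, pd.DataFrame(events)


def simulate_head_trajectory(model: TrajectoryModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a ground-truth Euler trajectory and its event log.

    Returns ``(trajectory, events)``: the trajectory has columns
    ``t, yaw, pitch, roll`` (degrees at ``model.dt`` sampling) and the event
    log one row per movement with onset/offset times and per-axis extents
    (``extent_yaw, extent_pitch, extent_roll``).  The ``rotation_table`` kind
    has no discrete events and returns an empty log.
    """
    rng = np.random.default_rng(model.seed)
    n = int(round(model.duration / model.dt))
    t = np.arange(n) * model.dt
    kind = model.kind
    if kind == "rotation_table":
        yaw = model.table_speed * t
        traj = pd.DataFrame(
            {"t": t, "yaw": yaw, "pitch": np.zeros(n), "roll": np.zeros(n)}
        )
        return traj, pd.DataFrame()
    if kind == "unconstrained":
        s_yaw, s_pitch, s_roll = model.displacement_sigma
        # yaw diffuses freely (azimuth is unbounded); pitch and roll revert
        # toward level so the head never approaches gimbal lock
        raw, events = _event_process(
            model, rng, 3, (s_yaw, s_pitch, s_roll), reversion=(0.0, 0.5, 0.5)
        )
        yaw, pitch, roll = raw[:, 0], raw[:, 1], raw[:, 2]
        # weak conjunctive coupling: roll co-moves with yaw
        roll = roll + model.yaw_roll_coupling * yaw
        if len(events):
            events["extent_2"] = events["extent_2"] + model.yaw_roll_coupling * events["extent_0"]
        traj = pd.DataFrame({"t": t, "yaw": yaw, "pitch": pitch, "roll": roll})
        events = _rename_events(events)
        return traj, events
    if kind in ("fick", "helmholtz", "listing"):
        sig = (model.gimbal_amplitude / 2.0, model.gimbal_amplitude / 2.0)
        raw, events = _event_process(model, rng, 2, sig, reversion=(0.5, 0.5))
        a = np.clip(raw[:, 0], -model.gimbal_amplitude, model.gimbal_amplitude)
        b = np.clip(raw[:, 1], -model.gimbal_amplitude, model.gimbal_amplitude)
        if kind == "fick":
            # yaw about the fixed vertical axis, pitch nested: exactly the
            # package Euler order with zero roll
            traj = pd.DataFrame({"t": t, "yaw": a, "pitch": b, "roll": np.zeros(n)})
        elif kind == "helmholtz":
            q = gimbal_quaternions(a, b, order="helmholtz")
            eul = donders.euler_from_quat(q)
            traj = pd.DataFrame({"t": t, "yaw": eul[:, 0], "pitch": eul[:, 1], "roll": eul[:, 2]})
        else:  # listing: zero-torsion quaternions
            q = listing_quaternions(a, b)
            eul = donders.euler_from_quat(q)
            traj = pd.DataFrame({"t": t, "yaw": eul[:, 0], "pitch": eul[:, 1], "roll": eul[:, 2]})
        events = _events_from_trajectory(events, traj)
        return traj, events
    raise ValueError(f"unknown trajectory kind: {kind!r}")


def _rename_events(events: pd.DataFrame) -> pd.DataFrame:
    if not len(events):
        return events
    return events.rename(
        columns={"extent_0": "extent_yaw", "extent_1": "extent_pitch", "extent_2": "extent_roll"}
    )


def _events_from_trajectory(events: pd.DataFrame, traj: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-axis extents of gimbal events from the Euler series."""
    if not len(events):
        return events
    dt = float(traj["t"].iloc[1] - traj["t"].iloc[0])
    out = events[["onset_t", "offset_t"]].copy()
    for axis in ("yaw", "pitch", "roll"):
        series = traj[axis].to_numpy()
        i0 = np.rint(out["onset_t"].to_numpy() / dt).astype(int)
        i1 = np.rint(out["offset_t"].to_numpy() / dt).astype(int)
        out[f"extent_{axis}"] = series[i1] - series[i0]
    return out


def gimbal_quaternions(outer_deg, inner_deg, order: str = "fick") -> np.ndarray:
    """Quaternions of nested-gimbal orientations with zero gimbal torsion.

    ``fick``: yaw (outer, fixed vertical axis) then pitch (inner, carried
    horizontal axis).  ``helmholtz``: pitch (outer, fixed horizontal axis)
    then yaw (inner, carried vertical axis).
    """
    a = np.radians(np.asarray(outer_deg, dtype=float)) / 2.0
    b = np.radians(np.asarray(inner_deg, dtype=float)) / 2.0
    if order == "fick":
        q_yaw = np.stack([np.cos(a), np.zeros_like(a), np.zeros_like(a), np.sin(a)], axis=-1)
        q_pitch = np.stack([np.cos(b), np.zeros_like(b), np.sin(b), np.zeros_like(b)], axis=-1)
        return donders.hemisphere_normalize(donders.quat_multiply(q_yaw, q_pitch))
    if order == "helmholtz":
        q_pitch = np.stack([np.cos(a), np.zeros_like(a), np.sin(a), np.zeros_like(a)], axis=-1)
        q_yaw = np.stack([np.cos(b), np.zeros_like(b), np.zeros_like(b), np.sin(b)], axis=-1)
        return donders.hemisphere_normalize(donders.quat_multiply(q_pitch, q_yaw))
    raise ValueError(f"unknown gimbal order: {order!r}")


def listing_quaternions(vertical_deg, horizontal_deg) -> np.ndarray:
    """Zero-torsion quaternions (qT = 0) from vertical/horizontal angles (deg)."""
    qv = np.sin(np.radians(np.asarray(vertical_deg, dtype=float)) / 2.0)
    qh = np.sin(np.radians(np.asarray(horizontal_deg, dtype=float)) / 2.0)
    q0 = np.sqrt(np.clip(1.0 - qv**2 - qh**2, 0.0, 1.0))
    return np.stack([q0, np.zeros_like(qv), qv, qh], axis=-1)


def simulate_imu(
    traj: pd.DataFrame,
    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0),
    gyro_noise_sd: float = 0.5,
    accel_noise_sd: float = 0.01,
    mag_noise_sd: float = 0.01,
    ref_field: tuple[float, float, float] = (1.0, 0.0, 0.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate the IMU stream that would have produced a trajectory.

    The head-frame angular velocity is the unique discrete rate satisfying the
    first-order DCM update between consecutive rotation matrices, so the
    noiseless zero-bias stream is inverted exactly (up to renormalization
    round-off) by the attitude estimator.  The accelerometer reads gravity
    ``R (0,0,1)`` and the magnetometer the reference field ``R (Bx,0,Bz)``,
    both in the head frame.  Gyro bias is in deg/s; white noise SDs are in
    deg/s (gyro) and in units of the unit-magnitude reference vectors
    (accelerometer/magnetometer, default 1% of magnitude).
    """
    rng = np.random.default_rng(seed)
    t = traj["t"].to_numpy(dtype=float)
    n = len(t)
    dt = float(np.median(np.diff(t)))
    Rs = np.empty((n, 3, 3))
    yaw = traj["yaw"].to_numpy(float)
    pitch = traj["pitch"].to_numpy(float)
    roll = traj["roll"].to_numpy(float)
    for i in range(n):
        Rs[i] = rotation_matrix_from_euler((yaw[i], pitch[i], roll[i]))
    # Head-frame rate per step: the rate whose discrete estimator step
    # (first-order update followed by renormalization) carries R(t) exactly
    # onto R(t+dt), found by a short fixed-point iteration seeded with the
    # tangent-scaled axis-angle of the relative rotation R(t) R^T(t+dt).
    from scipy.spatial.transform import Rotation

    A = np.einsum("nij,nkj->nik", Rs[:-1], Rs[1:])
    rotvec = Rotation.from_matrix(A).as_rotvec()
    theta = np.linalg.norm(rotvec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(theta > 1e-12, np.tan(np.minimum(theta, 1.5)) / theta, 1.0)
    omega = np.zeros((n, 3))
    omega[:-1] = rotvec * scale[:, np.newaxis] / dt
    for i in range(n - 1):
        w = omega[i]
        for _ in range(4):
            achieved = ahrs_renormalize(ahrs_dcm_update(Rs[i], np.degrees(w), dt))
            err_rot = Rotation.from_matrix(Rs[i + 1] @ achieved.T).as_rotvec()
            if np.linalg.norm(err_rot) < 1e-13:
                break
            # R(t+dt) = (I - [delta]x dt) achieved  =>  delta = -err/dt
            w = w - err_rot / dt
        omega[i] = w
    omega[-1] = omega[-2] if n > 1 else 0.0
    omega = np.degrees(omega)

    gravity = np.einsum("nij,j->ni", Rs, np.array([0.0, 0.0, 1.0]))
    mag = np.einsum("nij,j->ni", Rs, np.asarray(ref_field, dtype=float))

    omega_meas = omega + np.asarray(gyro_bias, float) + rng.normal(0.0, gyro_noise_sd, (n, 3))
    accel_meas = gravity + rng.normal(0.0, accel_noise_sd, (n, 3))
    mag_meas = mag + rng.normal(0.0, mag_noise_sd, (n, 3))
    return pd.DataFrame(
        {
            "t": t,
            "gx": omega_meas[:, 0],
            "gy": omega_meas[:, 1],
            "gz": omega_meas[:, 2],
            "ax": accel_meas[:, 0],
            "ay": accel_meas[:, 1],
            "az": accel_meas[:, 2],
            "mx": mag_meas[:, 0],
            "my": mag_meas[:, 1],
            "mz": mag_meas[:, 2],
        }
    )


def _poisson_spikes(rate_per_bin: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spikes from a per-bin rate (Hz) series."""
    counts = rng.poisson(np.clip(rate_per_bin, 0.0, None) * dt)
    times = []
    for i in np.flatnonzero(counts):
        times.append(i * dt + rng.uniform(0.0, dt, size=counts[i]))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def _burst_spikes(start: float, model: NeuronModel, rng: np.random.Generator) -> np.ndarray:
    """One burst: >= 3 spikes with ISIs jittered around 1/burst_rate."""
    n = 3 + rng.poisson(2.0)
    isis = (1.0 / model.burst_rate) * rng.uniform(0.7, 1.3, size=n - 1)
    return start + np.concatenate([[0.0], np.cumsum(isis)])


def _truncated_mean(center: float, half: float, sigma: float) -> float:
    """Mean of N(0, sigma) truncated to [center - half, center + half]."""
    from scipy.stats import norm

    a = (center - half) / sigma
    b = (center + half) / sigma
    denom = norm.cdf(b) - norm.cdf(a)
    if denom <= 0:
        return center
    return sigma * (norm.pdf(a) - norm.pdf(b)) / denom


def _selection_windows(model: NeuronModel, event_sigmas: np.ndarray) -> list[tuple[float, float] | None]:
    """Per-axis acceptance windows on event extents for a displacement cell.

    Each constrained axis gets a window of half-width
    ``tuning_halfwidth_factor * |preferred|`` whose center is shifted so that
    the *mean* extent of accepted events equals the preferred component
    exactly (a window centred on the preferred value would select events whose
    mean is shrunk toward zero, because small extents are more common).
    """
    from scipy.optimize import brentq

    windows: list[tuple[float, float] | None] = []
    for p, sigma in zip(model.preferred_vector, event_sigmas):
        if p == 0.0 or not np.isfinite(sigma) or sigma <= 0:
            windows.append(None)
            continue
        half = model.tuning_halfwidth_factor * abs(p)

        def bias(c, half=half, sigma=sigma, p=p):
            return _truncated_mean(c, half, sigma) - p

        lo, hi = p, p + np.sign(p) * (2.0 * half + sigma)
        if np.sign(p) < 0:
            lo, hi = hi, lo
        try:
            center = brentq(bias, lo, hi, xtol=1e-6)
        except ValueError:
            center = p
        windows.append((center - half, center + half))
    return windows


def _selects_event(extents: np.ndarray, windows) -> bool:
    for w, e in zip(windows, extents):
        if w is None:
            continue
        if not (w[0] <= e <= w[1]):
            return False
    return True


def simulate_spike_train(
    traj: pd.DataFrame,
    events: pd.DataFrame,
    model: NeuronModel,
) -> np.ndarray:
    """Simulate a spike train coupled to a trajectory and its event log.

    See :class:`NeuronModel` for the four cell kinds.  Spike times are in
    seconds within ``[0, duration)``, sorted.
    """
    rng = np.random.default_rng(model.seed)
    t = traj["t"].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    duration = t[-1] + dt
    n = len(t)
    kind = model.kind
    if kind == "untuned_poisson":
        return _poisson_spikes(np.full(n, model.baseline_rate), dt, rng)
    if kind == "displacement_tuned":
        spikes = [_poisson_spikes(np.full(n, model.baseline_rate), dt, rng)]
        ext_cols = ["extent_yaw", "extent_pitch", "extent_roll"]
        if len(events):
            sigmas = events[ext_cols].to_numpy(dtype=float).std(axis=0)
        else:
            sigmas = np.full(3, np.nan)
        windows = _selection_windows(model, sigmas)
        for _, ev in events.iterrows():
            extents = np.array([ev[c] for c in ext_cols])
            if not _selects_event(extents, windows):
                continue
            if rng.uniform() > model.reliability:
                continue
            start = float(ev["onset_t"]) - model.lead_time
            if start < 0:
                continue
            burst = _burst_spikes(start, model, rng)
            spikes.append(burst[burst < duration])
        return np.sort(np.concatenate(spikes))
    if kind == "ahv_tuned":
        from headmotion.ahv import compute_ahv, skewed_gaussian

        series = traj[model.ahv_axis].to_numpy(float)
        ahv = compute_ahv(series, dt=dt)
        amp, mu, sigma, gamma = model.ahv_params
        rate = model.baseline_rate + skewed_gaussian(ahv, amp, mu, sigma, gamma)
        return _poisson_spikes(rate, dt, rng)
    if kind == "azimuth_tuned":
        pref, kappa, peak = model.azimuth_params
        az = np.radians(traj["yaw"].to_numpy(float))
        rate = model.baseline_rate + peak * np.exp(
            kappa * (np.cos(az - np.radians(pref)) - 1.0)
        )
        return _poisson_spikes(rate, dt, rng)
    raise ValueError(f"unknown neuron kind: {kind!r}")
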