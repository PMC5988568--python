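"""Direction-cosine-matrix (DCM) attitude estimation for head-mounted IMUs.

The estimator integrates gyroscope angular velocity through a rotation matrix
``R`` that maps inertial-frame vectors into the head frame (``v_H = R v_I``),
renormalizes the matrix every step to enforce orthogonality, and corrects
gyroscope drift with accelerometer (pitch/roll) and magnetometer (yaw)
reference vectors through a proportional-plus-integral feedback loop.

Conventions
-----------
* Inertial frame: x north, y east, z down.  Head frame: x out the nose,
  y out the right ear, z out the bottom of the head.
* Euler angles (yaw ``psi`` about z, pitch ``theta`` about y, roll ``phi``
  about x) are *clockwise-positive* rotations and are expressed in degrees at
  every public boundary; all internal math is in radians.
* The Euler decomposition is ``R = Rx(phi) @ Ry(theta) @ Rz(psi)`` (yaw
  applied first), so gimbal lock occurs at pitch = +/-90 deg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS_HORIZONTAL = 1e-8
_EPS_VECTOR = 1e-12
GIMBAL_LOCK_TOL_DEG = 1e-6 * (180.0 / np.pi)  # |theta - 90 deg| below this -> lock


@dataclass(frozen=True)
class EulerAngles:
    """Yaw/pitch/roll triple in degrees (clockwise-positive)."""

    psi: float
    theta: float
    phi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.psi, self.theta, self.phi], dtype=float)


@dataclass
class DcmState:
    """Mutable state of the feedback loop: rotation matrix, integral term, gains."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    omega_I: np.ndarray = field(default_factory=lambda: np.zeros(3))  # rad/s
    kp_yaw: float = 1.2
    kp_pitchroll: float = 0.02
    ki_yaw: float = 0.001
    ki_pitchroll: float = 0.001


@dataclass
class AhrsConfig:
    """Configuration of a full AHRS run.

    ``ref_field`` is the inertial-frame geomagnetic reference ``(Bx, 0, Bz)``;
    only its direction matters.  The default is a purely horizontal field of
    unit magnitude pointing north (zero inclination).
    """

    kp_yaw: float = 1.2
    kp_pitchroll: float = 0.02
    ki_yaw: float = 0.001
    ki_pitchroll: float = 0.001
    ref_field: tuple[float, float, float] = (1.0, 0.0, 0.0)
    initial_euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    use_corrections: bool = True


def rotation_matrix_from_euler(angles) -> np.ndarray:
    """Rotation matrix mapping inertial-frame to head-frame coordinates.

    ``angles`` is an :class:`EulerAngles` or a ``(psi, theta, phi)`` sequence
    in degrees.  The matrix is the product ``Rx(phi) Ry(theta) Rz(psi)`` of the
    three clockwise-positive elementary frame rotations.
    """
    if isinstance(angles, EulerAngles):
        psi, theta, phi = angles.psi, angles.theta, angles.phi
    else:
        psi, theta, phi = angles
    ps, th, ph = np.radians([psi, theta, phi])
    cps, sps = np.cos(ps), np.sin(ps)
    cth, sth = np.cos(th), np.sin(th)
    cph, sph = np.cos(ph), np.sin(ph)
    return np.array(
        [
            [cth * cps, cth * sps, -sth],
            [sph * sth * cps - cph * sps, sph * sth * sps + cph * cps, sph * cth],
            [cph * sth * cps + sph * sps, cph * sth * sps - sph * cps, cph * cth],
        ]
    )


def euler_from_rotation_matrix(R: np.ndarray) -> tuple[EulerAngles, bool]:
    """Extract ``(EulerAngles, gimbal_lock)`` from a rotation matrix.

    ``phi = atan2(R23, R33)``, ``theta = -asin(R13)``, ``psi = atan2(R12, R11)``.
    The gimbal-lock flag is set (never raised) when pitch is within numerical
    tolerance of +/-90 deg, where yaw and roll are no longer distinct.
    """
    r13 = float(np.clip(R[0, 2], -1.0, 1.0))
    phi = np.degrees(np.arctan2(R[1, 2], R[2, 2]))
    theta = np.degrees(-np.arcsin(r13))
    psi = np.degrees(np.arctan2(R[0, 1], R[0, 0]))
    lock = bool(90.0 - abs(theta) < GIMBAL_LOCK_TOL_DEG)
    return EulerAngles(psi=psi, theta=theta, phi=phi), lock


def dcm_update(R: np.ndarray, omega_deg_s, dt: float) -> np.ndarray:
    """Advance the rotation matrix one time step from gyroscope rates.

    The transpose form of the kinematic update is
    ``R^T(t+dt) = R^T(t) (I + Omega_x dt)`` with ``Omega_x`` the cross-product
    matrix of the (corrected) head-frame angular velocity; stored as ``R`` this
    is the algebraically identical pre-multiplication
    ``R(t+dt) = (I + Omega_x dt)^T R(t)``.
    """
    wx, wy, wz = np.radians(np.asarray(omega_deg_s, dtype=float))
    update = np.array(
        [
            [1.0, -wz * dt, wy * dt],
            [wz * dt, 1.0, -wx * dt],
            [-wy * dt, wx * dt, 1.0],
        ]
    )
    return update.T @ R


def renormalize(R: np.ndarray) -> np.ndarray:
    """Restore orthonormality of a near-orthogonal rotation matrix.

    Splits the X/Y column dot-product error symmetrically between the two
    columns, rebuilds Z as their cross product, and applies one Taylor step of
    magnitude adjustment ``v <- (3 - v.v)/2 * v`` to each column.

    Raises
    ------
    ValueError
        If the X and Y columns are too far from orthogonal (|X.Y| >= 0.5);
        the state is considered corrupted rather than correctable.
    """
    X = R[:, 0].copy()
    Y = R[:, 1].copy()
    error = float(X @ Y)
    if abs(error) >= 0.5:
        raise ValueError(
            f"rotation matrix corrupted: |X.Y| = {abs(error):.3f} >= 0.5"
        )
    Xo = X - (error / 2.0) * Y
    Yo = Y - (error / 2.0) * X
    Zo = np.cross(Xo, Yo)
    Xn = 0.5 * (3.0 - Xo @ Xo) * Xo
    Yn = 0.5 * (3.0 - Yo @ Yo) * Yo
    Zn = 0.5 * (3.0 - Zo @ Zo) * Zo
    return np.column_stack([Xn, Yn, Zn])


def magnetometer_yaw(R: np.ndarray, mag) -> float:
    """Yaw (radians) implied by a head-frame magnetometer reading.

    Uses the current pitch/roll estimate from ``R`` to de-rotate the reading:
    ``tan(psi_m) = (sin(phi) Mz - cos(phi) My) /
    (cos(theta) Mx + sin(theta) sin(phi) My + sin(theta) cos(phi) Mz)``.
    """
    mx, my, mz = np.asarray(mag, dtype=float)
    phi = np.arctan2(R[1, 2], R[2, 2])
    theta = -np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
    num = np.sin(phi) * mz - np.cos(phi) * my
    den = (
        np.cos(theta) * mx
        + np.sin(theta) * np.sin(phi) * my
        + np.sin(theta) * np.cos(phi) * mz
    )
    return float(np.arctan2(num, den))


def yaw_correction(R: np.ndarray, mag, ref_field=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Head-frame yaw error vector ``e_Y`` from the magnetometer.

    The magnetometer yaw ``psi_m`` is compared against the DCM heading by the
    cross product, in the inertial frame, of the horizontal projection of the
    head x axis ``(R11, R12, 0)`` with the reference heading
    ``(cos psi_m, sin psi_m, 0)``; the result is rotated into the head frame.
    Returns a zero vector (with a log entry) when the horizontal projection is
    degenerate (pitch near +/-90 deg) or the magnetometer reading vanishes.
    """
    mag = np.asarray(mag, dtype=float)
    if float(np.linalg.norm(mag)) < _EPS_VECTOR:
        logger.warning("yaw_correction: near-zero magnetometer reading; skipping")
        return np.zeros(3)
    # ref_field enters only through its (Bx, 0, Bz) structure: the de-rotation
    # of Eq-form above is insensitive to inclination, so psi_m needs no Bz.
    del ref_field
    if np.hypot(R[0, 0], R[0, 1]) < _EPS_HORIZONTAL:
        logger.warning("yaw_correction: horizontal projection degenerate; skipping")
        return np.zeros(3)
    psi_m = magnetometer_yaw(R, mag)
    e_y_inertial = np.array(
        [0.0, 0.0, R[0, 0] * np.sin(psi_m) - R[0, 1] * np.cos(psi_m)]
    )
    return R @ e_y_inertial


def pitch_roll_correction(R: np.ndarray, accel) -> np.ndarray:
    """Head-frame pitch/roll error vector ``e_PR`` from the accelerometer.

    Cross product of the normalized accelerometer vector (assumed to measure
    gravity only) with the estimated inertial z axis viewed in the head frame,
    ``(R13, R23, R33)``.  The operand order is the one whose feedback sense
    *reduces* the attitude error under the additive correction of the update
    equation (as in reference AHRS implementations); the magnitude equals the
    sine of the tilt error either way.  Near-zero accelerometer magnitude
    (free fall or a dropout) yields a zero correction and a log entry.
    """
    a = np.asarray(accel, dtype=float)
    norm = float(np.linalg.norm(a))
    if norm < _EPS_VECTOR:
        logger.warning("pitch_roll_correction: near-zero accelerometer; skipping")
        return np.zeros(3)
    return np.cross(a / norm, R[:, 2])


def pi_feedback(
    state: DcmState, omega_gyro_deg_s, e_y, e_pr, dt: float
) -> np.ndarray:
    """Apply proportional-plus-integral drift feedback to the gyro rates.

    ``omega_P = KP_yaw e_Y + KP_pitchroll e_PR`` and the accumulated
    ``omega_I += (KI_yaw e_Y + KI_pitchroll e_PR) dt``; the corrected rate is
    ``omega_gyro + omega_P + omega_I``.  Returns the corrected angular
    velocity in deg/s and updates ``state.omega_I`` in place.
    """
    e_y = np.asarray(e_y, dtype=float)
    e_pr = np.asarray(e_pr, dtype=float)
    omega_p = state.kp_yaw * e_y + state.kp_pitchroll * e_pr
    state.omega_I = state.omega_I + (state.ki_yaw * e_y + state.ki_pitchroll * e_pr) * dt
    correction = omega_p + state.omega_I  # rad/s
    return np.asarray(omega_gyro_deg_s, dtype=float) + np.degrees(correction)


def run_ahrs(stream: pd.DataFrame, config: AhrsConfig | None = None) -> pd.DataFrame:
    """Run the full DCM estimator over an IMU stream.

    Parameters
    ----------
    stream
        DataFrame with columns ``t, gx, gy, gz, ax, ay, az, mx, my, mz``
        (gyro in deg/s, accelerometer/magnetometer in arbitrary units) sampled
        at a uniform rate; timestamps must be strictly increasing.
    config
        Gains, reference field and initial orientation; defaults to the
        standard gains with an identity initial attitude.

    Returns
    -------
    DataFrame with columns ``t, yaw, pitch, roll`` (degrees) and a boolean
    ``gimbal_lock`` column, one row per input sample.  Each cycle performs
    rotation update -> renormalization -> reference corrections -> PI feedback.
    """
    if config is None:
        config = AhrsConfig()
    if len(stream) == 0:
        raise ValueError("empty IMU stream")
    t = stream["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise ValueError("non-monotonic timestamps in IMU stream")
        dt = float(np.median(dts))
    else:
        dt = 0.02
    gyro = stream[["gx", "gy", "gz"]].to_numpy(dtype=float)
    accel = stream[["ax", "ay", "az"]].to_numpy(dtype=float)
    mag = stream[["mx", "my", "mz"]].to_numpy(dtype=float)

    psi0, theta0, phi0 = config.initial_euler
    state = DcmState(
        R=rotation_matrix_from_euler(EulerAngles(psi0, theta0, phi0)),
        kp_yaw=config.kp_yaw,
        kp_pitchroll=config.kp_pitchroll,
        ki_yaw=config.ki_yaw,
        ki_pitchroll=config.ki_pitchroll,
    )
    n = len(t)
    out = np.empty((n, 3))
    locks = np.zeros(n, dtype=bool)
    ang, locks[0] = euler_from_rotation_matrix(state.R)
    out[0] = [ang.psi, ang.theta, ang.phi]
    correction_deg = np.zeros(3)
    for i in range(1, n):
        omega = gyro[i - 1] + correction_deg
        state.R = renormalize(dcm_update(state.R, omega, dt))
        if config.use_corrections:
            e_y = yaw_correction(state.R, mag[i], config.ref_field)
            e_pr = pitch_roll_correction(state.R, accel[i])
            corrected = pi_feedback(state, np.zeros(3), e_y, e_pr, dt)
            correction_deg = corrected  # gyro part was zero: correction only
        ang, locks[i] = euler_from_rotation_matrix(state.R)
        out[i] = [ang.psi, ang.theta, ang.phi]
    return pd.DataFrame(
        {
            "t": t,
            "yaw": out[:, 0],
            "pitch": out[:, 1],
            "roll": out[:, 2],
            "gimbal_lock": locks,
        }
    )
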