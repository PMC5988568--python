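"""Quaternion representation of head orientation and Donders'-surface fitting.

Head orientations are expressed as unit quaternions
``q = (q0, qT, qV, qH) = cos(a/2) + sin(a/2) n`` with scalar part ``q0`` and a
vector part whose components are the torsional (x / roll), vertical (y /
pitch) and horizontal (z / yaw) rotation axes.  Only the northern hemisphere
(``q0 >= 0``) is used, so each physical orientation has a unique
representative.

Donders'-law adherence is quantified by fitting a surface ``qT = f(qV, qH)``
(a plane, a full second-order surface, or the one-parameter Fick form
``qT = s qV qH / q0``) and measuring the torsional standard deviation (Tsd) of
the residuals, converted to degrees of torsion.  A gimbal score ``s`` of -1
corresponds to a perfect Fick gimbal (horizontal axis fixed, vertical nested),
+1 to a Helmholtz gimbal, 0 to a Listing plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_UNIT_TOL = 1e-9


def quat_from_euler(psi, theta, phi) -> np.ndarray:
    """Unit quaternion(s) ``(q0, qT, qV, qH)`` from yaw/pitch/roll in degrees.

    Implements the closed-form combination for the z-y-x (yaw-first) rotation
    order with the z axis pointing down; the result is hemisphere-normalized
    (all four components negated wherever ``q0 < 0``).  Accepts scalars or
    equal-length arrays and returns shape ``(4,)`` or ``(n, 4)``.
    """
    ps = np.radians(np.asarray(psi, dtype=float)) / 2.0
    th = np.radians(np.asarray(theta, dtype=float)) / 2.0
    ph = np.radians(np.asarray(phi, dtype=float)) / 2.0
    cps, sps = np.cos(ps), np.sin(ps)
    cth, sth = np.cos(th), np.sin(th)
    cph, sph = np.cos(ph), np.sin(ph)
    q0 = cph * cth * cps + sph * sth * sps
    qt = sph * cth * cps - cph * sth * sps
    qv = cph * sth * cps + sph * cth * sps
    qh = cph * cth * sps - sph * sth * cps
    q = np.stack([q0, qt, qv, qh], axis=-1)
    return hemisphere_normalize(q)


def hemisphere_normalize(q: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so that ``q0 >= 0`` (northern hemisphere)."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., 0] < 0.0, -1.0, 1.0)
    return q * sign[..., np.newaxis]


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of quaternions in ``(q0, qT, qV, qH)`` order."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0, a1, a2, a3 = np.moveaxis(np.broadcast_to(a, np.broadcast_shapes(a.shape, b.shape)), -1, 0)
    b0, b1, b2, b3 = np.moveaxis(np.broadcast_to(b, np.broadcast_shapes(a.shape, b.shape)), -1, 0)
    return np.stack(
        [
            a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    """Conjugate (= inverse for unit quaternions)."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def euler_from_quat(q: np.ndarray) -> np.ndarray:
    """Yaw/pitch/roll (degrees) from quaternion(s) via the rotation matrix."""
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    q0, qt, qv, qh = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # Elements of the inertial->head matrix needed for the Euler extraction.
    r11 = 1.0 - 2.0 * (qv**2 + qh**2)
    r12 = 2.0 * (qt * qv + q0 * qh)
    r13 = 2.0 * (qt * qh - q0 * qv)
    r23 = 2.0 * (qv * qh + q0 * qt)
    r33 = 1.0 - 2.0 * (qt**2 + qv**2)
    psi = np.degrees(np.arctan2(r12, r11))
    theta = np.degrees(-np.arcsin(np.clip(r13, -1.0, 1.0)))
    phi = np.degrees(np.arctan2(r23, r33))
    out = np.stack([psi, theta, phi], axis=-1)
    return out[0] if single else out


def _fit_plane(q: np.ndarray) -> np.ndarray:
    """Least-squares coefficients (a1, a2, a3) of qT = a1 + a2 qV + a3 qH."""
    design = np.column_stack([np.ones(len(q)), q[:, 2], q[:, 3]])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate plane fit: qV/qH samples are collinear")
    coeffs, *_ = np.linalg.lstsq(design, q[:, 1], rcond=None)
    return coeffs


def _plane_angle_deg(c1: np.ndarray, c2: np.ndarray) -> float:
    """Angle between two planes qT = a1 + a2 qV + a3 qH via their normals."""
    n1 = np.array([1.0, -c1[1], -c1[2]])
    n2 = np.array([1.0, -c2[1], -c2[2]])
    cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class PrimaryRotation:
    """Outcome of re-referencing orientations to the primary position."""

    quats: np.ndarray
    a1_initial: float
    plane_initial: np.ndarray
    plane_rereferenced: np.ndarray
    plane_angle_diff_deg: float
    primary: np.ndarray


def rotate_to_primary(q: np.ndarray) -> PrimaryRotation:
    """Rotate a quaternion cloud so the reference position is the primary one.

    Fits the displacement plane ``qT = a1 + a2 qV + a3 qH``; when ``a1`` is
    nonzero the reference orientation does not satisfy the Listing corollary
    and the cloud is first right-multiplied by the inverse of
    ``h = (sqrt(1 - a1^2), a1, 0, 0)``.  The plane is refit, its unit normal
    ``V = (V1, V2, V3)`` computed, and the cloud left-multiplied by the inverse
    of the primary-position quaternion ``p = (V1, 0, V3, -V2)``.  A single
    re-referencing pass is performed; the angular difference between the
    initial and re-referenced planes is reported.
    """
    q = hemisphere_normalize(np.asarray(q, dtype=float))
    if len(q) < 50:
        raise ValueError("rotate_to_primary requires at least 50 samples")
    coeffs0 = _fit_plane(q)
    a1 = float(coeffs0[0])
    a1c = float(np.clip(a1, -1.0, 1.0))
    h = np.array([np.sqrt(1.0 - a1c**2), a1c, 0.0, 0.0])
    qh = quat_multiply(q, quat_conjugate(h))
    coeffs_h = _fit_plane(qh)
    normal = np.array([1.0, coeffs_h[1], coeffs_h[2]])
    v1, v2, v3 = normal / np.linalg.norm(normal)
    p = np.array([v1, 0.0, v3, -v2])
    p = p / np.linalg.norm(p)
    rotated = hemisphere_normalize(quat_multiply(quat_conjugate(p), qh))
    return PrimaryRotation(
        quats=rotated,
        a1_initial=a1,
        plane_initial=coeffs0,
        plane_rereferenced=coeffs_h,
        plane_angle_diff_deg=_plane_angle_deg(coeffs0, coeffs_h),
        primary=p,
    )


@dataclass
class DondersFit:
    """Donders-surface fit: coefficients, twist/gimbal scores and Tsd (deg)."""

    order: str
    coeffs: np.ndarray
    tsd_deg: float
    twist_score: float | None = None
    gimbal_score: float | None = None
    n_points: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def torsion_degrees(residual_qt: np.ndarray) -> np.ndarray:
    """Convert a torsional quaternion residual to degrees of torsion (2 asin r)."""
    return np.degrees(2.0 * np.arcsin(np.clip(residual_qt, -1.0, 1.0)))


def fit_donders_surface(
    q: np.ndarray,
    order: str = "first",
    n_points: int = 1000,
    seed: int | None = None,
) -> DondersFit:
    """Least-squares fit of a Donders surface to a quaternion cloud.

    ``order`` selects the surface: ``"first"`` fits the plane
    ``qT = a1 + a2 qV + a3 qH``; ``"second"`` adds the quadratic terms
    ``a4 qV^2 + a5 qV qH + a6 qH^2`` (``a5`` is the twist score); ``"fick"``
    fits the one-parameter gimbal form ``qT = s qV qH / q0``.  When more than
    ``n_points`` samples are available a uniform random subsample of that size
    (seeded) is fit, mirroring the fixed-budget fitting of large sessions.

    Tsd is the standard deviation of the torsional residuals, each converted
    exactly to a torsion angle ``2 asin(r)`` in degrees.
    """
    q = np.asarray(q, dtype=float)
    if len(q) < 100:
        raise ValueError("fit_donders_surface requires at least 100 samples")
    if len(q) > n_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(q), size=n_points, replace=False)
        q = q[idx]
    qt, qv, qh, q0 = q[:, 1], q[:, 2], q[:, 3], q[:, 0]
    twist = gimbal = None
    if order == "first":
        design = np.column_stack([np.ones(len(q)), qv, qh])
    elif order == "second":
        design = np.column_stack([np.ones(len(q)), qv, qh, qv**2, qv * qh, qh**2])
    elif order == "fick":
        design = (qv * qh / q0)[:, np.newaxis]
    else:
        raise ValueError(f"unknown surface order: {order!r}")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: orientation samples degenerate")
    coeffs, *_ = np.linalg.lstsq(design, qt, rcond=None)
    pred = design @ coeffs
    resid = qt - pred
    if order == "second":
        twist = float(coeffs[4])
    elif order == "fick":
        gimbal = float(coeffs[0])
    tsd = float(np.std(torsion_degrees(resid)))
    return DondersFit(
        order=order,
        coeffs=coeffs,
        tsd_deg=tsd,
        twist_score=twist,
        gimbal_score=gimbal,
        n_points=len(q),
        residuals=resid,
    )
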