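"""Unit tests for the direction-cosine-matrix attitude estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.spatial.transform import Rotation

from conftest import geodesic_error_deg, wrap_deg
from headmotion import ahrs
from headmotion.ahrs import (
    AhrsConfig,
    DcmState,
    EulerAngles,
    dcm_update,
    euler_from_rotation_matrix,
    pi_feedback,
    pitch_roll_correction,
    renormalize,
    rotation_matrix_from_euler,
    run_ahrs,
    yaw_correction,
)


def closed_form_matrix(psi, theta, phi):
    """Element-by-element closed form of the yaw-pitch-roll frame matrix."""
    ps, th, ph = np.radians([psi, theta, phi])
    return np.array(
        [
            [np.cos(th) * np.cos(ps), np.cos(th) * np.sin(ps), -np.sin(th)],
            [
                np.sin(ph) * np.sin(th) * np.cos(ps) - np.cos(ph) * np.sin(ps),
                np.sin(ph) * np.sin(th) * np.sin(ps) + np.cos(ph) * np.cos(ps),
                np.sin(ph) * np.cos(th),
            ],
            [
                np.cos(ph) * np.sin(th) * np.cos(ps) + np.sin(ph) * np.sin(ps),
                np.cos(ph) * np.sin(th) * np.sin(ps) - np.sin(ph) * np.cos(ps),
                np.cos(ph) * np.cos(th),
            ],
        ]
    )


class TestRotationMatrix:
    def test_zero_rotation_is_identity(self):
        np.testing.assert_allclose(
            rotation_matrix_from_euler(EulerAngles(0.0, 0.0, 0.0)), np.eye(3)
        )

    def test_pure_yaw_quarter_turn(self):
        R = rotation_matrix_from_euler((90.0, 0.0, 0.0))
        assert R[0, 0] == pytest.approx(0.0, abs=1e-15)
        assert R[0, 1] == pytest.approx(1.0)
        assert R[1, 0] == pytest.approx(-1.0)
        assert R[1, 1] == pytest.approx(0.0, abs=1e-15)
        assert R[2, 2] == pytest.approx(1.0)

    @given(
        psi=st.floats(-179.0, 179.0),
        theta=st.floats(-89.0, 89.0),
        phi=st.floats(-179.0, 179.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_closed_form_and_is_orthogonal(self, psi, theta, phi):
        R = rotation_matrix_from_euler((psi, theta, phi))
        np.testing.assert_allclose(R, closed_form_matrix(psi, theta, phi), atol=1e-12)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_frame_convention(self, rng):
        """Independent cross-check: transpose of the scipy ZYX active matrix."""
        for _ in range(20):
            psi, theta, phi = rng.uniform([-170, -85, -170], [170, 85, 170])
            R = rotation_matrix_from_euler((psi, theta, phi))
            Rs = Rotation.from_euler("ZYX", [psi, theta, phi], degrees=True)
            np.testing.assert_allclose(R, Rs.as_matrix().T, atol=1e-12)


class TestEulerExtraction:
    def test_identity_gives_zero_angles(self):
        ang, lock = euler_from_rotation_matrix(np.eye(3))
        assert (ang.psi, ang.theta, ang.phi) == (0.0, 0.0, 0.0)
        assert not lock

    def test_round_trip_recovers_angles(self, rng):
        for _ in range(1000):
            psi, theta, phi = rng.uniform([-179, -89, -179], [179, 89, 179])
            ang, lock = euler_from_rotation_matrix(
                rotation_matrix_from_euler((psi, theta, phi))
            )
            assert not lock
            np.testing.assert_allclose(
                [ang.psi, ang.theta, ang.phi], [psi, theta, phi], atol=1e-9
            )

    @pytest.mark.parametrize("pitch", [90.0, -90.0])
    def test_gimbal_lock_flagged_at_vertical_pitch(self, pitch):
        _, lock = euler_from_rotation_matrix(
            rotation_matrix_from_euler((30.0, pitch, 10.0))
        )
        assert lock


class TestDcmUpdate:
    def test_zero_rate_leaves_matrix_unchanged(self, rng):
        R = rotation_matrix_from_euler(rng.uniform(-40, 40, 3))
        np.testing.assert_array_equal(dcm_update(R, (0.0, 0.0, 0.0), 0.02), R)

    def test_constant_yaw_rate_integrates_to_eighty_degrees(self):
        R = np.eye(3)
        for _ in range(50):
            R = renormalize(dcm_update(R, (0.0, 0.0, 80.0), 0.02))
        ang, _ = euler_from_rotation_matrix(R)
        assert ang.psi == pytest.approx(80.0, abs=0.05)

    def test_single_step_error_is_second_order_in_dt(self):
        """Halving dt must quarter the one-step discrepancy vs the exact map."""
        omega = np.radians([30.0, -50.0, 70.0])
        errs = []
        for dt in (0.02, 0.01):
            Om = np.array(
                [
                    [0.0, -omega[2], omega[1]],
                    [omega[2], 0.0, -omega[0]],
                    [-omega[1], omega[0], 0.0],
                ]
            )
            exact = expm(Om * dt).T  # pre-multiplication convention
            approx = dcm_update(np.eye(3), np.degrees(omega), dt)
            errs.append(np.abs(approx - exact).max())
        assert errs[1] == pytest.approx(errs[0] / 4.0, rel=0.1)


class TestRenormalize:
    def test_orthonormal_matrix_unchanged(self, rng):
        R = rotation_matrix_from_euler(rng.uniform(-60, 60, 3))
        np.testing.assert_allclose(renormalize(R), R, atol=1e-12)

    def test_dot_product_error_reduced_quadratically(self):
        # unit columns with X.Y = 0.1
        X = np.array([1.0, 0.0, 0.0])
        Y = np.array([0.1, np.sqrt(1.0 - 0.01), 0.0])
        R = np.column_stack([X, Y, np.cross(X, Y)])
        out = renormalize(R)
        assert abs(out[:, 0] @ out[:, 1]) <= 0.25 * 0.1**2

    def test_magnitude_adjustment_contracts_norm_error_quadratically(self):
        """One Taylor step v <- (3 - v.v)/2 v leaves an O(eps^2) residual."""
        eps = 0.05
        R = (1.0 + eps) * np.eye(3)
        out = renormalize(R)
        taylor = 0.5 * (3.0 - (1.0 + eps) ** 2) * (1.0 + eps)
        # X and Y columns follow the closed-form Taylor value exactly ...
        np.testing.assert_allclose(np.linalg.norm(out[:, :2], axis=0), taylor, rtol=1e-12)
        # ... whose residual is quadratic in the initial norm error; the Z
        # column is rebuilt from the scaled X and Y so its error scales as
        # the square of the doubled norm error
        np.testing.assert_allclose(np.linalg.norm(out[:, :2], axis=0), 1.0, atol=2.5 * eps**2)
        assert abs(np.linalg.norm(out[:, 2]) - 1.0) < 2.5 * (2 * eps) ** 2

    def test_rejects_badly_corrupted_matrix(self):
        X = np.array([1.0, 0.0, 0.0])
        Y = np.array([0.6, 0.8, 0.0])  # X.Y = 0.6
        with pytest.raises(ValueError, match="corrupted"):
            renormalize(np.column_stack([X, Y, np.cross(X, Y)]))

    def test_orthogonality_preserved_along_a_run(self):
        R = np.eye(3)
        rng = np.random.default_rng(0)
        for _ in range(500):
            R = renormalize(dcm_update(R, rng.uniform(-50, 50, 3), 0.02))
            pair = max(
                abs(R[:, 0] @ R[:, 1]), abs(R[:, 0] @ R[:, 2]), abs(R[:, 1] @ R[:, 2])
            )
            assert pair < 1e-6


class TestReferenceCorrections:
    def test_yaw_correction_zero_when_aligned(self):
        R = rotation_matrix_from_euler((25.0, 5.0, -10.0))
        mag = R @ np.array([1.0, 0.0, 0.0])  # field consistent with attitude
        np.testing.assert_allclose(yaw_correction(R, mag), np.zeros(3), atol=1e-12)

    def test_yaw_correction_matches_direct_cross_product(self):
        # level orientation, DCM yaw 10 deg, true field yaw 0
        R = rotation_matrix_from_euler((10.0, 0.0, 0.0))
        mag = np.array([1.0, 0.0, 0.0])
        e_y = yaw_correction(R, mag)
        psi_m = 0.0
        expected_z = R[0, 0] * np.sin(psi_m) - R[0, 1] * np.cos(psi_m)
        # level attitude: head-frame z equals inertial z
        assert e_y[2] == pytest.approx(expected_z, abs=1e-12)
        assert e_y[:2] == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_yaw_correction_degenerate_at_vertical_pitch(self):
        R = rotation_matrix_from_euler((0.0, 90.0, 0.0))
        np.testing.assert_array_equal(yaw_correction(R, (1.0, 0.0, 0.0)), np.zeros(3))

    def test_pitch_roll_correction_zero_when_aligned(self):
        R = rotation_matrix_from_euler((40.0, 20.0, -30.0))
        accel = R @ np.array([0.0, 0.0, 1.0])
        np.testing.assert_allclose(
            pitch_roll_correction(R, 5.0 * accel), np.zeros(3), atol=1e-12
        )

    def test_pitch_roll_correction_magnitude_is_sine_of_tilt(self):
        R = np.eye(3)
        tilt = np.radians(5.0)
        accel = np.array([0.0, np.sin(tilt), np.cos(tilt)])  # tilted about head x
        e_pr = pitch_roll_correction(R, accel)
        assert np.linalg.norm(e_pr) == pytest.approx(np.sin(tilt), abs=1e-9)

    def test_near_zero_accel_gives_zero_correction(self):
        np.testing.assert_array_equal(
            pitch_roll_correction(np.eye(3), (0.0, 0.0, 0.0)), np.zeros(3)
        )


class TestPiFeedback:
    def test_zero_errors_pass_gyro_through(self):
        state = DcmState()
        out = pi_feedback(state, (10.0, -5.0, 3.0), np.zeros(3), np.zeros(3), 0.02)
        np.testing.assert_allclose(out, [10.0, -5.0, 3.0])
        np.testing.assert_array_equal(state.omega_I, np.zeros(3))

    def test_integral_term_grows_linearly(self):
        state = DcmState()
        e_y = np.array([0.0, 0.0, 0.01])
        n, dt = 250, 0.02
        for _ in range(n):
            pi_feedback(state, np.zeros(3), e_y, np.zeros(3), dt)
        np.testing.assert_allclose(
            state.omega_I, state.ki_yaw * n * dt * e_y, rtol=1e-12
        )

    def test_default_gains_match_reference_values(self):
        state = DcmState()
        assert (state.kp_yaw, state.kp_pitchroll) == (1.2, 0.02)
        assert (state.ki_yaw, state.ki_pitchroll) == (0.001, 0.001)


def _static_stream(n, gyro=(0.0, 0.0, 0.0)):
    t = np.arange(n) * 0.02
    gx, gy, gz = gyro
    return pd.DataFrame(
        {
            "t": t,
            "gx": gx,
            "gy": gy,
            "gz": gz,
            "ax": 0.0,
            "ay": 0.0,
            "az": 1.0,
            "mx": 1.0,
            "my": 0.0,
            "mz": 0.0,
        }
    )


class TestRunAhrs:
    def test_static_ideal_stream_has_zero_jitter_and_drift(self):
        est = run_ahrs(_static_stream(500))
        assert est[["yaw", "pitch", "roll"]].abs().to_numpy().max() < 1e-9
        assert not est["gimbal_lock"].any()

    def test_rejects_non_monotonic_timestamps(self):
        stream = _static_stream(10)
        stream.loc[5, "t"] = stream.loc[3, "t"]
        with pytest.raises(ValueError, match="timestamps"):
            run_ahrs(stream)

    def test_rotation_table_mean_step_at_80_deg_s(self):
        from headmotion.synth import TrajectoryModel, simulate_head_trajectory, simulate_imu

        traj, _ = simulate_head_trajectory(
            TrajectoryModel(kind="rotation_table", duration=4.0, table_speed=80.0)
        )
        imu = simulate_imu(traj, gyro_noise_sd=0.0, accel_noise_sd=0.0, mag_noise_sd=0.0)
        est = run_ahrs(imu)
        steps = np.diff(np.unwrap(np.radians(est["yaw"])))
        assert np.degrees(steps.mean()) == pytest.approx(1.6, abs=0.01)

    def test_yaw_bias_bounded_with_magnetometer_unbounded_without(self):
        stream = _static_stream(6000, gyro=(0.0, 0.0, 1.0))
        est = run_ahrs(stream)
        assert est["yaw"].iloc[-3000:].abs().max() < 1.0  # steady-state error
        est_off = run_ahrs(stream, AhrsConfig(use_corrections=False))
        assert abs(est_off["yaw"].iloc[-1]) > 100.0  # ~1 deg/s * 120 s

    def test_pitch_bias_bounded_with_accelerometer_unbounded_without(self):
        stream = _static_stream(9000, gyro=(0.0, 0.5, 0.0))
        est = run_ahrs(stream)
        assert est["pitch"].abs().max() < 15.0
        est_off = run_ahrs(stream, AhrsConfig(use_corrections=False))
        assert abs(est_off["pitch"].iloc[-1]) > 80.0

    def test_initial_orientation_is_configurable(self):
        est = run_ahrs(
            _static_stream(1), AhrsConfig(initial_euler=(30.0, -10.0, 5.0))
        )
        np.testing.assert_allclose(
            est[["yaw", "pitch", "roll"]].iloc[0], [30.0, -10.0, 5.0], atol=1e-9
        )

    def test_trajectories_below_89_deg_pitch_never_flag_gimbal_lock(
        self, foraging_trajectory
    ):
        from headmotion.synth import simulate_imu

        traj, _ = foraging_trajectory
        sub = traj.iloc[:3000].reset_index(drop=True)
        assert sub["pitch"].abs().max() < 89.0
        imu = simulate_imu(sub, gyro_noise_sd=0.0, accel_noise_sd=0.0, mag_noise_sd=0.0)
        est = run_ahrs(imu)
        assert not est["gimbal_lock"].any()
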