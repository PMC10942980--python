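import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from overstride.imu import (ImuAngleSeries, MountingInfo, OrientationSeries,
                            align_sign, angles_at_fc, mean_quaternion,
                            quat_to_matrix, sagittal_angle_per_frame_method,
                            sagittal_angle_static_method,
                            static_pose_calibrate)


def _series_from_rotation(rot, rate=120.0, segment="shank", gyro=None):
    q = rot.as_quat()
    quat = np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])
    return OrientationSeries(quat=quat, sample_rate=rate, segment=segment,
                             gyro=gyro)


def _planar_trial(theta_deg, mount=None, drift_deg=None, rate=120.0):
    """Orientation stream for planar motion, optional mounting + drift."""
    rot = Rotation.from_euler("y", -np.radians(theta_deg)[:, None])
    if drift_deg is not None:
        rot = Rotation.from_euler("z", np.radians(drift_deg)[:, None]) * rot
    if mount is not None:
        rot = rot * mount
    return _series_from_rotation(rot, rate=rate)


def _standing_then_motion(n_stand=240, rate=120.0):
    t = np.arange(n_stand + 600) / rate
    theta = np.zeros_like(t)
    m = t >= n_stand / rate
    theta[m] = 25 * np.sin(2 * np.pi * 1.3 * (t[m] - n_stand / rate))
    return t, theta


class TestQuaternionOps:
    def test_identity_quaternion(self):
        np.testing.assert_allclose(quat_to_matrix([1, 0, 0, 0]), np.eye(3),
                                   atol=1e-15)

    def test_90deg_about_z_maps_x_to_y(self):
        q = [np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)]
        np.testing.assert_allclose(quat_to_matrix(q) @ [1, 0, 0], [0, 1, 0],
                                   atol=1e-12)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError):
            quat_to_matrix([0, 0, 0, 0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_unit_quaternion_gives_orthogonal_matrix(self, seed):
        q = np.random.default_rng(seed).normal(size=4)
        q /= np.linalg.norm(q)
        R = quat_to_matrix(q)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_mean_quaternion_sign_invariant(self, rng):
        q = rng.normal(size=(20, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        flip = q.copy()
        flip[::2] *= -1
        np.testing.assert_allclose(np.abs(mean_quaternion(q)),
                                   np.abs(mean_quaternion(flip)), atol=1e-12)

    def test_q_and_minus_q_same_angles(self):
        _, theta = _standing_then_motion()
        s = _planar_trial(theta)
        mounting = static_pose_calibrate(s, (0.2, 1.4))
        a1 = sagittal_angle_static_method(s, mounting).theta
        s2 = OrientationSeries(quat=-s.quat, sample_rate=120.0)
        a2 = sagittal_angle_static_method(s2, mounting).theta
        np.testing.assert_allclose(a1, a2, atol=1e-9)


class TestStaticCalibration:
    def test_arbitrary_mounting_reads_zero_at_standing(self, rng):
        _, theta = _standing_then_motion()
        mount = Rotation.from_rotvec(rng.normal(0, 0.3, 3))
        s = _planar_trial(theta, mount=mount)
        mounting = static_pose_calibrate(s, (0.2, 1.4))
        ang = sagittal_angle_static_method(s, mounting)
        np.testing.assert_allclose(ang.theta[:200], 0.0, atol=1e-8)

    def test_two_mountings_give_identical_angles(self):
        _, theta = _standing_then_motion()
        axis = np.array([0.0, 1.0, 0.0])
        m1 = Rotation.from_rotvec(np.radians(10) * axis)
        m2 = Rotation.from_rotvec(np.radians(40) * axis)  # 30 deg apart
        out = []
        for m in (m1, m2):
            s = _planar_trial(theta, mount=m)
            mounting = static_pose_calibrate(s, (0.2, 1.4))
            out.append(sagittal_angle_static_method(s, mounting).theta)
        np.testing.assert_allclose(out[0], out[1], atol=1e-8)

    def test_motion_in_window_rejected(self):
        _, theta = _standing_then_motion()
        gyro = np.full((len(theta), 3), 30.0)
        s = _planar_trial(theta)
        s.gyro = gyro
        with pytest.raises(ValueError, match="motion detected"):
            static_pose_calibrate(s, (0.2, 1.4))

    def test_short_window_rejected(self):
        _, theta = _standing_then_motion()
        with pytest.raises(ValueError, match="0.5"):
            static_pose_calibrate(_planar_trial(theta), (0.2, 0.4))


class TestPerFrameMethod:
    def test_matches_static_method_without_drift(self, rng):
        _, theta = _standing_then_motion()
        mount = Rotation.from_rotvec(rng.normal(0, 0.1, 3))
        s = _planar_trial(theta, mount=mount)
        mounting = static_pose_calibrate(s, (0.2, 1.4))
        a_static = sagittal_angle_static_method(s, mounting).theta
        a_pf = sagittal_angle_per_frame_method(s, mounting).theta
        np.testing.assert_allclose(a_pf, a_static, atol=1e-6)

    def test_heading_drift_annihilated(self, rng):
        t, theta = _standing_then_motion()
        mount = Rotation.from_rotvec(rng.normal(0, 0.1, 3))
        drift = np.where(t > 2.0, 30.0 * (t - 2.0) / (t[-1] - 2.0), 0.0)
        s = _planar_trial(theta, mount=mount, drift_deg=drift)
        mounting = static_pose_calibrate(s, (0.2, 1.4))
        a_pf = sagittal_angle_per_frame_method(s, mounting).theta
        a_static = sagittal_angle_static_method(s, mounting).theta
        np.testing.assert_allclose(a_pf, theta, atol=1e-6)
        assert np.max(np.abs(a_static - theta)) > 1.0

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.floats(min_value=-180, max_value=180))
    def test_invariant_to_static_heading_rotation(self, heading):
        _, theta = _standing_then_motion()
        drift = np.full_like(theta, heading)
        s = _planar_trial(theta, drift_deg=drift)
        # calibration sees the same heading, so it cancels there too; add
        # heading only after standing to emulate a reference change
        s2 = _planar_trial(theta)
        mounting = static_pose_calibrate(s2, (0.2, 1.4))
        a = sagittal_angle_per_frame_method(s, mounting).theta
        np.testing.assert_allclose(a, theta, atol=1e-6)

    def test_out_of_plane_tilt_bounded_error(self):
        _, theta = _standing_then_motion()
        rot = (Rotation.from_euler("x", np.full(len(theta), np.radians(3.0))[:, None])
               * Rotation.from_euler("y", -np.radians(theta)[:, None]))
        s = _series_from_rotation(rot)
        mounting = MountingInfo(segment="shank",
                                joint_axis_local=[0, 1, 0],
                                static_offset=[1, 0, 0, 0])
        a = sagittal_angle_per_frame_method(s, mounting).theta
        err = np.max(np.abs(a - theta))
        assert 0 < err < 1.0

    def test_joint_axis_near_vertical_rejected(self):
        _, theta = _standing_then_motion()
        s = _planar_trial(theta)
        mounting = MountingInfo(segment="shank",
                                joint_axis_local=[0, 0.02, 0.9998],
                                static_offset=[1, 0, 0, 0])
        with pytest.raises(ValueError, match="vertical"):
            sagittal_angle_per_frame_method(s, mounting)


class TestAnglesAtFC:
    def _angles(self):
        return ImuAngleSeries(theta=np.array([10.0, 12.0, 14.0]),
                              sample_rate=100.0, t0=0.0)

    def test_fc_on_sample(self):
        assert angles_at_fc(self._angles(), [0.01])[0] == pytest.approx(12.0)

    def test_fc_between_samples(self):
        assert angles_at_fc(self._angles(), [0.005])[0] == pytest.approx(11.0)

    def test_fc_outside_support_flagged_nan(self):
        out = angles_at_fc(self._angles(), [0.5])
        assert np.isnan(out[0])

    def test_align_sign(self):
        t = np.linspace(0, 1, 100)
        a = np.sin(2 * np.pi * t)
        assert align_sign(a, a) == 1.0
        assert align_sign(-a, a) == -1.0
        with pytest.raises(ValueError):
            align_sign(np.zeros(10), np.zeros(10))
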