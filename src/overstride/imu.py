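"""Sagittal segment angles from IMU orientation quaternions.

Two calibration schemes are implemented:

``static_pose`` — the segment orientation is referenced to a standing pose
(mean orientation over a quiet window), and the sagittal angle is the
planar rotation about the lab mediolateral axis.  Simple, but any heading
drift of the fused orientation (error accumulating about gravity) leaks
into the angle over time.

``per_frame_redefinition`` — at every frame the global frame is redefined
with one axis along the (projected-to-horizontal) joint axis and one
against gravity, and the sagittal angle is the Euler angle about the joint
axis.  Because the frame is rebuilt from the *current* joint-axis heading,
any rotation about gravity — static or slowly accumulating — cancels
exactly for planar motion.  This assumes hinge-like joints with the sensor
axis aligned to the joint axis; out-of-plane motion produces bounded
cross-talk.

Conventions: lab frame X forward, Y left (mediolateral), Z up.  A segment
pitched forward by ``theta`` (distal end ahead) corresponds to the rotation
``R_y(-theta)`` from the standing pose; thigh/shank angles are relative to
vertical, the foot angle relative to horizontal with the standing (foot
flat) pose defining zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "OrientationSeries",
    "MountingInfo",
    "ImuAngleSeries",
    "quat_normalize",
    "quat_continuity",
    "quat_to_matrix",
    "mean_quaternion",
    "static_pose_calibrate",
    "sagittal_angle_static_method",
    "sagittal_angle_per_frame_method",
    "angles_at_fc",
    "align_sign",
]

_RAD2DEG = 180.0 / np.pi
UP = np.array([0.0, 0.0, 1.0])


@dataclasses.dataclass
class OrientationSeries:
    """Unit-quaternion (sensor-to-global) time series for one segment's IMU.

    ``quat`` is (n, 4) in (w, x, y, z) order; ``t0`` is the stream start in
    the reference clock (shifted by the sync stage).  ``gyro`` (deg/s,
    sensor frame) is optional and used only for stillness checks.
    """

    quat: np.ndarray
    sample_rate: float
    t0: float = 0.0
    segment: str = ""
    gyro: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.quat = quat_continuity(quat_normalize(np.asarray(self.quat,
                                                              dtype=float)))

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.quat)) / self.sample_rate

    def __len__(self) -> int:
        return len(self.quat)

    def rotations(self) -> Rotation:
        """As a scipy Rotation (handles wxyz -> xyzw ordering)."""
        q = self.quat
        return Rotation.from_quat(
            np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))


@dataclasses.dataclass
class MountingInfo:
    """Sensor-to-segment mounting metadata for one IMU.

    joint_axis_local: unit mediolateral (joint) axis in the sensor frame.
    static_offset: sensor-to-global orientation at the standing pose
    (w, x, y, z); referencing to it makes the standing angle exactly zero.
    axis_sign: +1/-1 so positive angle = distal end forward (resolved
    against a known forward swing; see :func:`align_sign`).
    """

    segment: str
    joint_axis_local: np.ndarray
    static_offset: np.ndarray
    axis_sign: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.joint_axis_local, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("joint_axis_local must be nonzero")
        self.joint_axis_local = a / n
        self.static_offset = quat_normalize(
            np.asarray(self.static_offset, dtype=float))


@dataclasses.dataclass
class ImuAngleSeries:
    """Sagittal angle series (degrees) for one segment."""

    theta: np.ndarray
    sample_rate: float
    t0: float = 0.0
    segment: str = ""
    method: str = "static_pose"

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.theta)) / self.sample_rate


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q)
    norm = np.linalg.norm(q2, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero quaternion")
    out = q2 / norm
    return out[0] if single else out


def quat_continuity(q: np.ndarray) -> np.ndarray:
    """Flip signs so consecutive quaternions satisfy dot(q_t, q_{t-1}) >= 0."""
    q = np.array(q, dtype=float, copy=True)
    if q.ndim == 1:
        return q
    dots = np.sum(q[1:] * q[:-1], axis=1)
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix from a (w, x, y, z) unit quaternion."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("zero quaternion")
    w, x, y, z = q / n
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def _matrices(series: OrientationSeries) -> np.ndarray:
    return series.rotations().as_matrix()


def mean_quaternion(q: np.ndarray) -> np.ndarray:
    """Barycenter of unit quaternions (largest eigenvector of sum qq^T).

    Invariant to per-sample sign flips.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    M = q.T @ q
    w, v = np.linalg.eigh(M)
    m = v[:, -1]
    if m[0] < 0:
        m = -m
    return m / np.linalg.norm(m)


def static_pose_calibrate(orientation: OrientationSeries,
                          standing_window: tuple,
                          gyro_still_thresh: float = 10.0) -> MountingInfo:
    """Calibrate mounting from a quiet standing window.

    The window must be at least 0.5 s with gyroscope norm below
    ``gyro_still_thresh`` deg/s throughout (checked when gyro data is
    present).  The static offset is the mean orientation over the window;
    the joint axis in the sensor frame is the lab mediolateral axis pulled
    back through the static offset.
    """
    t0, t1 = standing_window
    if t1 - t0 < 0.5:
        raise ValueError("standing window must be at least 0.5 s")
    sel = (orientation.time >= t0) & (orientation.time <= t1)
    if not np.any(sel):
        raise ValueError("standing window outside series support")
    if orientation.gyro is not None:
        gnorm = np.linalg.norm(orientation.gyro[sel], axis=1)
        if np.any(gnorm > gyro_still_thresh):
            raise ValueError(
                f"motion detected in standing window "
                f"(gyro norm up to {gnorm.max():.1f} deg/s)")
    q0 = mean_quaternion(orientation.quat[sel])
    R0 = quat_to_matrix(q0)
    axis_local = R0.T @ np.array([0.0, 1.0, 0.0])
    return MountingInfo(segment=orientation.segment,
                        joint_axis_local=axis_local, static_offset=q0)


def _planar_angle(R_seg: np.ndarray) -> np.ndarray:
    """Sagittal angle (deg) from segment rotation matrices (n, 3, 3).

    Mediolateral-first Euler decomposition R = R_y(a) R_x(b) R_z(c):
    a = atan2(R[0,2], R[2,2]); theta = -a so that a segment pitched
    forward (R = R_y(-theta)) reads +theta.  Heading error composed on
    the left does NOT drop out of this decomposition — that leakage is
    exactly what the per-frame redefinition removes.
    """
    theta = np.arctan2(-R_seg[:, 0, 2], R_seg[:, 2, 2])
    return np.unwrap(theta) * _RAD2DEG


def sagittal_angle_static_method(orientation: OrientationSeries,
                                 mounting: MountingInfo) -> ImuAngleSeries:
    """Sagittal angle via the standing-pose calibration.

    Segment orientation = q(t) * static_offset^-1; the angle is the planar
    rotation about the lab mediolateral axis.  Reads exactly 0 deg during
    the standing pose; susceptible to heading drift.
    """
    R = _matrices(orientation)
    R0 = quat_to_matrix(mounting.static_offset)
    R_seg = R @ R0.T
    theta = mounting.axis_sign * _planar_angle(R_seg)
    return ImuAngleSeries(theta=theta, sample_rate=orientation.sample_rate,
                          t0=orientation.t0, segment=orientation.segment,
                          method="static_pose")


def sagittal_angle_per_frame_method(orientation: OrientationSeries,
                                    mounting: MountingInfo,
                                    gravity_up: np.ndarray = UP,
                                    min_axis_tilt_deg: float = 5.0
                                    ) -> ImuAngleSeries:
    """Sagittal angle via per-frame global-frame redefinition.

    At each frame the joint axis is mapped to the global frame, projected
    onto the horizontal plane to form the mediolateral axis of a redefined
    global frame whose vertical axis opposes gravity; the sagittal angle is
    the Euler angle about that axis (mediolateral-first decomposition).
    Rotations about gravity — including accumulated heading drift — cancel
    exactly for planar motion.

    Raises if the joint axis comes within ``min_axis_tilt_deg`` of vertical
    (frame reconstruction degenerate).
    """
    g = np.asarray(gravity_up, dtype=float)
    g = g / np.linalg.norm(g)
    R = _matrices(orientation)
    a_global = R @ mounting.joint_axis_local  # (n, 3)
    vert = a_global @ g
    horiz = np.sqrt(np.maximum(0.0, 1.0 - vert ** 2))
    min_horiz = np.sin(np.radians(min_axis_tilt_deg))
    if np.any(horiz < min_horiz):
        k = int(np.argmax(horiz < min_horiz))
        raise ValueError(
            f"joint axis within {min_axis_tilt_deg} deg of vertical "
            f"at frame {k}")
    y_new = a_global - vert[:, None] * g
    y_new /= np.linalg.norm(y_new, axis=1, keepdims=True)
    z_new = np.broadcast_to(g, y_new.shape)
    x_new = np.cross(y_new, z_new)
    # basis matrices B with columns (x', y', z'); R' = B^T R R0^T
    B = np.stack([x_new, y_new, z_new], axis=2)
    R0 = quat_to_matrix(mounting.static_offset)
    R_seg = np.transpose(B, (0, 2, 1)) @ R @ R0.T
    theta = mounting.axis_sign * _planar_angle(R_seg)
    # constant offset so the standing reference reads zero even if the
    # static pose itself was slightly tilted in the redefined frame
    return ImuAngleSeries(theta=theta, sample_rate=orientation.sample_rate,
                          t0=orientation.t0, segment=orientation.segment,
                          method="per_frame_redefinition")


def align_sign(theta_imu: np.ndarray, theta_reference: np.ndarray) -> float:
    """Resolve the joint-axis sign against a known maneuver.

    Returns +1 if the IMU angle correlates positively with the reference
    angle over the maneuver (conventions agree), otherwise -1.
    """
    a = np.asarray(theta_imu, float) - np.mean(theta_imu)
    b = np.asarray(theta_reference, float) - np.mean(theta_reference)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("no signal to resolve axis sign")
    return 1.0 if float(a @ b) >= 0 else -1.0


def angles_at_fc(angle_series: ImuAngleSeries, fc_times) -> np.ndarray:
    """Angle at each foot-contact instant by linear interpolation.

    FC times outside the series support yield NaN (stride flagged for
    exclusion) rather than an error, so one truncated stride does not
    abort a trial.
    """
    t = angle_series.time
    fc = np.asarray(fc_times, dtype=float)
    out = np.interp(fc, t, angle_series.theta)
    outside = (fc < t[0]) | (fc > t[-1])
    if np.any(outside):
        import logging
        logging.getLogger("overstride").warning(
            "%d FC instants outside IMU angle support; flagged NaN",
            int(outside.sum()))
        out = np.where(outside, np.nan, out)
    return out
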