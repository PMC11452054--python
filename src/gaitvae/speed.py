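"""Gait speed from a foot-worn IMU via zero-velocity-updated dead reckoning.

Seven steps, in order: the recording is resampled to 100 Hz and offset
corrected (preprocessing module), gait events are detected, sensor
orientation is estimated with a complementary filter (gyroscope integration,
tilt-corrected toward the accelerometer gravity direction during stance),
acceleration is rotated to the global frame and gravity removed, horizontal
velocity is obtained by integration, zero-velocity updates pin the velocity
to zero in mid-stance windows with linear de-trending of the drift between
updates, and the corrected velocity is integrated to position. Gait speed is
the summed per-span displacement magnitude divided by the walk duration.

Distance is accumulated as the norm of the horizontal displacement between
consecutive zero-velocity anchors, so heading changes on a shuttle walking
path do not cancel out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .core import GRAVITY, GaitEvents, ImuRecording

ZUPT_WINDOW_FRACTION = 0.4  # central fraction of each stance used as anchor
TILT_GAIN = 0.02  # complementary-filter accelerometer gain during stance


@dataclass
class OrientationSeries:
    """Per-sample unit quaternions (x, y, z, w) mapping sensor -> global."""

    quat: np.ndarray  # (n, 4), scipy convention
    fs: float

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.quat, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ValueError("quaternions must be unit norm")

    def as_rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)


@dataclass
class SpeedResult:
    velocity_ap: np.ndarray  # m/s per sample, along the direction of travel
    position_ap: np.ndarray  # m per sample
    total_distance: float  # m
    gait_speed: float  # m/s
    zupt_intervals: np.ndarray  # (m, 2) sample index ranges used as anchors
    velocity_xy: np.ndarray = field(default=None)  # (n, 2) corrected horizontal


def _quat_mul(q, r):
    x1, y1, z1, w1 = q
    x2, y2, z2, w2 = r
    return (
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    )


def _quat_from_rotvec(rx, ry, rz):
    angle = math.sqrt(rx * rx + ry * ry + rz * rz)
    if angle < 1e-12:
        return (0.5 * rx, 0.5 * ry, 0.5 * rz, 1.0)
    s = math.sin(0.5 * angle) / angle
    return (rx * s, ry * s, rz * s, math.cos(0.5 * angle))


def estimate_orientation(rec: ImuRecording, events: GaitEvents) -> OrientationSeries:
    """Complementary-filter orientation estimate (sensor -> global).

    The quaternion is propagated by gyroscope integration; during stance
    intervals the estimated gravity direction is nudged toward the measured
    accelerometer direction with gain :data:`TILT_GAIN` per sample (gain 0
    during swing). The gyroscope must already be offset corrected. The
    initial tilt is taken from the mean accelerometer direction over the
    first 0.3 s.
    """
    n = len(rec)
    dt = 1.0 / rec.fs
    stance = events.stance_mask(n)

    a0 = rec.acc[: max(int(0.3 * rec.fs), 1)].mean(axis=0)
    a0 = a0 / np.linalg.norm(a0)
    # initial rotation taking the measured gravity direction to global +z
    axis = np.cross(a0, [0.0, 0.0, 1.0])
    s = np.linalg.norm(axis)
    c = float(a0 @ [0.0, 0.0, 1.0])
    if s < 1e-12:
        q = (0.0, 0.0, 0.0, 1.0) if c > 0 else (1.0, 0.0, 0.0, 0.0)
    else:
        rot = Rotation.from_rotvec(axis / s * math.atan2(s, c))
        q = tuple(rot.as_quat())

    gyr_rad = np.radians(rec.gyr) * dt
    acc = rec.acc
    out = np.empty((n, 4))
    for i in range(n):
        out[i] = q
        # body-frame propagation
        q = _quat_mul(q, _quat_from_rotvec(gyr_rad[i, 0], gyr_rad[i, 1], gyr_rad[i, 2]))
        if stance[i]:
            ax, ay, az = acc[i]
            na = math.sqrt(ax * ax + ay * ay + az * az)
            if na > 1e-9:
                ax, ay, az = ax / na, ay / na, az / na
                # predicted sensor-frame gravity direction: conj(q) * z * q
                x, y, z, w = q
                gx = 2.0 * (x * z - w * y)
                gy = 2.0 * (y * z + w * x)
                gz = 1.0 - 2.0 * (x * x + y * y)
                # rotate prediction toward measurement
                ex = gy * az - gz * ay
                ey = gz * ax - gx * az
                ez = gx * ay - gy * ax
                q = _quat_mul(q, _quat_from_rotvec(-TILT_GAIN * ex,
                                                   -TILT_GAIN * ey,
                                                   -TILT_GAIN * ez))
        norm = math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
        q = (q[0] / norm, q[1] / norm, q[2] / norm, q[3] / norm)
    return OrientationSeries(quat=out, fs=rec.fs)


def global_linear_acceleration(rec: ImuRecording, orient: OrientationSeries) -> np.ndarray:
    """Rotate acceleration to the global frame and remove gravity.

    Returns (n, 3) in m/s^2 with columns anterior-posterior, medio-lateral,
    vertical.
    """
    rotated = orient.as_rotation().apply(rec.acc)
    rotated[:, 2] -= 1.0
    return rotated * GRAVITY


def zupt_windows(events: GaitEvents) -> np.ndarray:
    """Central 40% window of each stance interval, as (m, 2) index ranges."""
    wins = []
    for s, e in events.stance_intervals:
        length = e - s
        pad = (1.0 - ZUPT_WINDOW_FRACTION) / 2.0
        w0 = s + int(math.floor(pad * length))
        w1 = e - int(math.floor(pad * length))
        if w1 <= w0:
            w0 = s + length // 2
            w1 = w0 + 1
        wins.append((w0, w1))
    return np.asarray(wins, dtype=int).reshape(-1, 2)


def integrate_with_zupt(acc: np.ndarray, events: GaitEvents,
                        fs: float = 100.0) -> SpeedResult:
    """Integrate horizontal acceleration to velocity/position with ZUPT.

    ``acc`` is an (n,) anterior-posterior series or an (n, 2) horizontal
    series in m/s^2. Velocity is obtained by cumulative trapezoidal
    integration; inside each mid-stance window it is reset to zero and the
    accumulated drift is removed by linear de-trending across the preceding
    inter-anchor span. Total distance is the sum of per-span displacement
    magnitudes; gait speed is total distance over the full duration.
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float).T).T  # (n, k)
    n, k = acc.shape
    if events.stance_intervals.shape[0] < 2:
        raise ValueError("ZUPT impossible: need at least two stance intervals")
    dt = 1.0 / fs
    wins = zupt_windows(events)
    wins = wins[(wins[:, 0] >= 0) & (wins[:, 1] <= n)]
    if wins.shape[0] < 2:
        raise ValueError("ZUPT impossible: anchors outside the signal")

    v_raw = cumulative_trapezoid(acc, dx=dt, initial=0.0, axis=0)
    centers = ((wins[:, 0] + wins[:, 1] - 1) // 2).astype(int)
    idx = np.arange(n)
    v_corr = np.empty_like(v_raw)
    for j in range(k):
        knots = np.array([v_raw[w0:w1, j].mean() for w0, w1 in wins])
        v_corr[:, j] = v_raw[:, j] - np.interp(idx, centers, knots)
    for w0, w1 in wins:
        v_corr[w0:w1] = 0.0

    pos = cumulative_trapezoid(v_corr, dx=dt, initial=0.0, axis=0)
    bounds = np.concatenate([[0], centers, [n - 1]])
    disp = np.diff(pos[bounds], axis=0)  # (m+1, k)
    span_len = np.linalg.norm(disp, axis=1)
    total = float(span_len.sum())

    # signed velocity along each span's direction of travel
    v_ap = np.zeros(n)
    for b0, b1, d in zip(bounds[:-1], bounds[1:], disp):
        nd = np.linalg.norm(d)
        u = d / nd if nd > 1e-12 else np.zeros(k)
        v_ap[b0:b1 + 1] = v_corr[b0:b1 + 1] @ u
    pos_ap = cumulative_trapezoid(v_ap, dx=dt, initial=0.0)

    duration = n * dt
    return SpeedResult(velocity_ap=v_ap, position_ap=pos_ap,
                       total_distance=total, gait_speed=total / duration,
                       zupt_intervals=wins, velocity_xy=v_corr)


def estimate_gait_speed(rec: ImuRecording, events: GaitEvents) -> SpeedResult:
    """Full chain: orientation -> global acceleration -> ZUPT integration.

    ``rec`` must be the 100-Hz offset-corrected recording whose ``events``
    were detected by the preprocessing pipeline.
    """
    orient = estimate_orientation(rec, events)
    lin = global_linear_acceleration(rec, orient)
    return integrate_with_zupt(lin[:, :2], events, fs=rec.fs)
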