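"""Phone orientation from Madgwick sensor fusion and Earth-frame rotation.

The Earth-fixed frame used throughout the package is X = medio-lateral,
Y = vertical (up), Z = anterior-posterior; a stationary accelerometer reads
the +Y reaction to gravity rotated into the body frame.  The Euler convention
follows the smartphone one: roll is rotation about the device Z-axis, pitch
about X, yaw about Y, composed intrinsically as R = Ry(yaw) Rx(pitch) Rz(roll).

Orientation is estimated with the Madgwick gradient-descent complementary
filter for MARG (gyro + accelerometer + magnetometer) arrays: the quaternion
is propagated by gyro integration and corrected along the normalized gradient
of the squared error between the measured gravity/field directions and the
ones predicted by the current quaternion.  The magnetic reference is
re-derived each step from the measured field ("field flattening"), so only
the horizontal field direction — magnetic north, mapped to +Z — constrains
yaw and hard-iron inclination errors do not leak into roll/pitch.

Quaternions are scalar-first (w, x, y, z) and map body to Earth coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .imu_io import UniformImuRecording

GRAVITY = 9.8  # m/s^2, vertical +Y in the Earth frame


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first)

def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array([
        pw * qw - px * qx - py * qy - pz * qz,
        pw * qx + px * qw + py * qz - pz * qy,
        pw * qy - px * qz + py * qw + pz * qx,
        pw * qz + px * qy - py * qx + pz * qw,
    ])


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (body -> Earth) for a scalar-first unit quaternion."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate body-frame vector(s) into the Earth frame by quaternion q."""
    return quat_to_matrix(q) @ np.asarray(v)


def euler_to_quat(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Quaternion for intrinsic yaw(Y) -> pitch(X) -> roll(Z) angles in degrees."""
    r = Rotation.from_euler("YXZ", [yaw, pitch, roll], degrees=True)
    x, y, z, w = r.as_quat()
    return np.array([w, x, y, z])


def to_euler(q: np.ndarray) -> tuple:
    """(roll, pitch, yaw) in degrees under the device convention.

    Roll is rotation about Z, pitch about X, yaw about Y; yaw in (-180, 180].
    Near gimbal lock (|pitch| > 89 deg) the decomposition is ill-conditioned;
    values are still returned.
    """
    w, x, y, z = quat_normalize(np.asarray(q, dtype=float))
    yaw, pitch, roll = Rotation.from_quat([x, y, z, w]).as_euler("YXZ", degrees=True)
    return float(roll), float(pitch), float(yaw)


def circular_median_deg(angles_deg: np.ndarray) -> float:
    """Median of angles in degrees, robust to wrap-around at +/-180.

    Angles are unwrapped around their circular mean before the ordinary
    median; the result is reported in (-180, 180].
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    mean = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    centered = np.angle(np.exp(1j * (a - mean)))
    med = np.degrees(mean + np.median(centered))
    med = (med + 180.0) % 360.0 - 180.0
    return float(med if med != -180.0 else 180.0)


# ---------------------------------------------------------------------------
# Madgwick MARG update

def _jacobian_ref(q: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Jacobian of u(q) = R(q)^T d with respect to q (3x4), scalar-first."""
    w, x, y, z = q
    dx, dy, dz = d
    # columns are (dR/dq_k)^T d for q_k in (w, x, y, z)
    return 2.0 * np.array([
        [dy * z - dz * y, dy * y + dz * z, -2 * dx * y + dy * x - dz * w, -2 * dx * z + dy * w + dz * x],
        [-dx * z + dz * x, dx * y - 2 * dy * x + dz * w, dx * x + dz * z, -dx * w - 2 * dy * z + dz * y],
        [dx * y - dy * x, dx * z - dy * w - 2 * dz * x, dx * w + dy * z - 2 * dz * y, dx * x + dy * y],
    ])


def madgwick_step(
    q: np.ndarray,
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray | None,
    dt: float,
    beta: float = 0.1,
) -> np.ndarray:
    """One Madgwick MARG update; returns the re-normalized quaternion.

    Zero-norm accelerometer (or magnetometer) samples disable the
    corresponding correction for this step, falling back to gyro-only
    integration when neither reference is usable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = np.asarray(q, dtype=float)
    qdot = 0.5 * quat_multiply(q, np.array([0.0, *gyro]))

    R = quat_to_matrix(q)
    residuals = []
    jacobians = []

    a_norm = np.linalg.norm(accel) if accel is not None else 0.0
    if a_norm > 1e-12:
        a_hat = np.asarray(accel, dtype=float) / a_norm
        g_ref = np.array([0.0, 1.0, 0.0])
        residuals.append(R.T @ g_ref - a_hat)
        jacobians.append(_jacobian_ref(q, g_ref))

        m_norm = np.linalg.norm(mag) if mag is not None else 0.0
        if m_norm > 1e-12:
            m_hat = np.asarray(mag, dtype=float) / m_norm
            h = R @ m_hat  # measured field in the Earth frame
            b_ref = np.array([0.0, h[1], np.hypot(h[0], h[2])])
            b_n = np.linalg.norm(b_ref)
            if b_n > 1e-12:
                b_ref /= b_n
                residuals.append(R.T @ b_ref - m_hat)
                jacobians.append(_jacobian_ref(q, b_ref))

    if residuals:
        f = np.concatenate(residuals)
        J = np.vstack(jacobians)
        grad = J.T @ f
        g_norm = np.linalg.norm(grad)
        if g_norm > 1e-12:
            qdot = qdot - beta * grad / g_norm

    return quat_normalize(q + qdot * dt)


def _triad_init(accel: np.ndarray, mag: np.ndarray | None) -> np.ndarray:
    """Initial quaternion from the first accelerometer/magnetometer sample.

    The Earth up direction in body coordinates is the normalized accelerometer
    reading; magnetic north (+Z) is the horizontal part of the field.  Without
    a usable magnetometer, heading is arbitrary (chosen so yaw ~ 0).
    """
    up = np.asarray(accel, dtype=float)
    n = np.linalg.norm(up)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0, 0.0])
    up = up / n
    north = None
    if mag is not None and np.linalg.norm(mag) > 1e-9:
        m = np.asarray(mag, dtype=float)
        horiz = m - np.dot(m, up) * up
        if np.linalg.norm(horiz) > 1e-9:
            north = horiz / np.linalg.norm(horiz)
    if north is None:
        cand = np.array([0.0, 0.0, 1.0])
        horiz = cand - np.dot(cand, up) * up
        if np.linalg.norm(horiz) < 1e-9:
            cand = np.array([1.0, 0.0, 0.0])
            horiz = cand - np.dot(cand, up) * up
        north = horiz / np.linalg.norm(horiz)
    east = np.cross(up, north)
    # rows of R(q)^T ... columns of R are body axes in Earth coords; rows of R
    # are Earth axes in body coords: Earth X (medio-lateral) = Y x Z.
    ml = np.cross(up, north)
    R = np.vstack([ml, up, north])
    x, y, z, w = Rotation.from_matrix(R).as_quat()
    return np.array([w, x, y, z])


@dataclass
class OrientationSeries:
    """Per-sample orientation quaternions with derived Euler angles."""

    quaternions: np.ndarray  # (n, 4) scalar-first, body -> Earth
    fs: float
    warmup_s: float = 0.0
    yaw_referenced: bool = True  # False when run without magnetometer
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.quaternions.shape[0]

    @property
    def warmup_samples(self) -> int:
        return int(round(self.warmup_s * self.fs))

    @property
    def euler(self) -> np.ndarray:
        """(n, 3) array of (roll, pitch, yaw) in degrees."""
        q = self.quaternions
        r = Rotation.from_quat(np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))
        ypr = r.as_euler("YXZ", degrees=True)
        return ypr[:, ::-1]


@dataclass
class EarthFrameRecording:
    """Uniformly sampled acceleration in the Earth-fixed frame.

    Axes: X medio-lateral, Y vertical (up), Z anterior-posterior.  When
    ``gravity_removed`` the constant (0, 9.8, 0) reaction has been subtracted.
    """

    rate: float
    accel_earth: np.ndarray
    gravity_removed: bool
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.accel_earth.shape[0]

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate


def estimate_orientation(
    rec: UniformImuRecording,
    beta: float = 0.1,
    warmup: float = 5.0,
    use_mag: bool = True,
) -> OrientationSeries:
    """Run Madgwick fusion over a uniform recording.

    The filter is initialized from the first accelerometer/magnetometer sample
    (TRIAD-style), so the ``warmup`` period mainly absorbs noise settling; it
    is flagged on the series and excluded from gait analysis downstream.
    Without a magnetometer the IMU-only variant runs and yaw is unreferenced.
    """
    n = len(rec)
    dt = 1.0 / rec.rate
    have_mag = use_mag and np.any(np.linalg.norm(rec.mag, axis=1) > 1e-9)
    q = _triad_init(rec.accel[0], rec.mag[0] if have_mag else None)
    quats = np.empty((n, 4))
    quats[0] = q
    for i in range(1, n):
        q = madgwick_step(
            q,
            rec.gyro[i],
            rec.accel[i],
            rec.mag[i] if have_mag else None,
            dt,
            beta=beta,
        )
        quats[i] = q
    return OrientationSeries(
        quaternions=quats,
        fs=rec.rate,
        warmup_s=warmup,
        yaw_referenced=bool(have_mag),
        meta={"beta": beta},
    )


def rotate_to_earth(
    rec: UniformImuRecording,
    ori: OrientationSeries,
    remove_gravity: bool = True,
) -> EarthFrameRecording:
    """Rotate body-frame acceleration into the Earth frame sample by sample."""
    if len(rec) != len(ori):
        raise ValueError(f"recording has {len(rec)} samples but orientation has {len(ori)}")
    q = ori.quaternions
    r = Rotation.from_quat(np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))
    accel_earth = r.apply(rec.accel)
    if remove_gravity:
        accel_earth = accel_earth - np.array([0.0, GRAVITY, 0.0])
    return EarthFrameRecording(
        rate=rec.rate,
        accel_earth=accel_earth,
        gravity_removed=remove_gravity,
        start_time=rec.start_time,
        meta={"warmup_s": ori.warmup_s, "yaw_referenced": ori.yaw_referenced},
    )
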