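"""Sensor calibration, quaternion orientation estimation and feature signals.

The detection variables are four physical signals derived from a calibrated
6-DOF recording:

* ``A(t)`` — acceleration norm in g,
* ``W(t)`` — rotational-speed norm in rad/s,
* ``rho(t)`` — tilt angle in rad, the angle between the device's vertical
  axis (carried by the estimated orientation quaternion) and world gravity,
* ``rho_dot(t)`` — tilt rate in rad/s by central finite difference.

Orientation is estimated with a gradient-descent complementary filter:
gyroscope integration by the first-order quaternion derivative, corrected
each step along the gradient of a gravity-direction objective built from the
accelerometer, and renormalised every step.  Quaternions are Hamilton,
scalar-first, and rotate device-frame vectors into the world frame; the
tilt angle is identical whether one reads ``q* g q`` as gravity expressed in
the device frame or as the device vertical expressed in the world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import atan2, cos, sin, sqrt

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AlignmentError,
    DegenerateGeometryError,
    EmptyInputError,
    InsufficientDataError,
    NotStationaryError,
)
from .io_formats import ImuRecording

#: Default gradient-correction gain of the orientation filter.  The
#: detectors are threshold-trained, which absorbs moderate sensitivity to
#: this value; 0.1 is the widely used published default for this filter
#: family.
DEFAULT_FILTER_GAIN = 0.1


@dataclass(frozen=True)
class AccelCalibration:
    """Accelerometer correction: ``a_true = gain_matrix @ (a_meas - bias)``.

    ``gain_matrix`` is upper triangular (scale factors on the diagonal,
    cross-axial coupling / axis misalignment above it), which makes the
    nine gain-and-bias parameters identifiable from static poses alone.
    """

    bias: np.ndarray
    gain_matrix: np.ndarray

    def apply(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return (self.gain_matrix @ (a - self.bias).T).T

    @classmethod
    def identity(cls) -> "AccelCalibration":
        return cls(bias=np.zeros(3), gain_matrix=np.eye(3))

    def to_dict(self) -> dict:
        return {"bias": [float(v) for v in self.bias],
                "gain_matrix": [[float(v) for v in row]
                                for row in self.gain_matrix]}

    @classmethod
    def from_dict(cls, d: dict) -> "AccelCalibration":
        return cls(bias=np.asarray(d["bias"], dtype=float),
                   gain_matrix=np.asarray(d["gain_matrix"], dtype=float))


@dataclass(frozen=True)
class GyroCalibration:
    """Gyroscope correction: static bias subtraction plus an optional
    integral drift-feedback gain used inside the orientation filter."""

    static_bias: np.ndarray
    drift_gain: float = 0.0

    def __post_init__(self):
        if self.drift_gain < 0:
            raise ValueError("drift_gain must be >= 0")

    def apply(self, w: np.ndarray) -> np.ndarray:
        return np.asarray(w, dtype=float) - self.static_bias

    def to_dict(self) -> dict:
        return {"static_bias": [float(v) for v in self.static_bias],
                "drift_gain": float(self.drift_gain)}

    @classmethod
    def from_dict(cls, d: dict) -> "GyroCalibration":
        return cls(static_bias=np.asarray(d["static_bias"], dtype=float),
                   drift_gain=float(d.get("drift_gain", 0.0)))


@dataclass
class FeatureSignals:
    """The four detection feature series on a common sample grid."""

    A: np.ndarray
    W: np.ndarray
    rho: np.ndarray
    rho_dot: np.ndarray
    fs: float

    def __post_init__(self):
        n = len(self.A)
        for name in ("W", "rho", "rho_dot"):
            if len(getattr(self, name)) != n:
                raise AlignmentError(f"feature series {name} length mismatch")

    def get(self, source: str) -> np.ndarray:
        try:
            return {"A": self.A, "W": self.W, "rho": self.rho,
                    "rho_dot": self.rho_dot}[source]
        except KeyError:
            raise KeyError(f"unknown feature source {source!r}") from None

    def __len__(self) -> int:
        return len(self.A)


def calibrate_accelerometer(poses: np.ndarray, tol: float = 1e-8,
                            max_iter: int = 100) -> AccelCalibration:
    """Fit bias and gain from static poses by iterative least squares.

    Each row of *poses* is the mean measured acceleration (in g) of one
    static orientation.  Because the magnitude of gravity is known, the
    corrected pose means must lie on the unit sphere; the residual
    ``||T (p - b)||^2 - 1`` is driven to zero over the nine parameters of an
    upper-triangular gain matrix ``T`` and the bias ``b``.  No external
    equipment is required — only enough distinct poses (>= 9) to constrain
    the parameters.
    """
    poses = np.asarray(poses, dtype=float)
    if poses.ndim != 2 or poses.shape[1] != 3:
        raise ValueError("poses must be an (m, 3) array")
    if poses.shape[0] < 9:
        raise InsufficientDataError(
            f"need >= 9 static poses to constrain bias + gain, got {poses.shape[0]}"
        )
    if np.linalg.matrix_rank(poses - poses.mean(axis=0), tol=1e-9) < 3:
        raise DegenerateGeometryError(
            "static poses are rank-deficient (identical or coplanar); "
            "they cannot constrain a full calibration"
        )

    def unpack(x):
        T = np.array([[x[0], x[1], x[2]],
                      [0.0, x[3], x[4]],
                      [0.0, 0.0, x[5]]])
        return T, x[6:9]

    def residual(x):
        T, b = unpack(x)
        c = (T @ (poses - b).T).T
        return np.einsum("ij,ij->i", c, c) - 1.0

    x0 = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0])
    result = least_squares(residual, x0, xtol=tol, ftol=tol, gtol=tol,
                           max_nfev=max_iter * len(x0))
    T, b = unpack(result.x)
    if abs(np.linalg.det(T)) < 1e-8:
        raise DegenerateGeometryError("fitted gain matrix is singular")
    return AccelCalibration(bias=np.asarray(b), gain_matrix=T)


def calibrate_gyroscope(segment: np.ndarray, variance_floor: float = 1e-3,
                        drift_gain: float = 0.0) -> GyroCalibration:
    """Estimate the static gyroscope bias from a stationary segment.

    The per-axis variance must stay below *variance_floor* (rad^2/s^2) for
    the segment to qualify as stationary; the bias is then the per-axis
    mean of the segment.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[1] != 3:
        raise ValueError("segment must be an (n, 3) array")
    if segment.shape[0] == 0:
        raise EmptyInputError("empty stationary segment")
    var = segment.var(axis=0)
    if np.any(var > variance_floor):
        raise NotStationaryError(
            f"segment variance {var.max():.3g} rad^2/s^2 exceeds the "
            f"immobility floor {variance_floor:.3g}"
        )
    return GyroCalibration(static_bias=segment.mean(axis=0),
                           drift_gain=drift_gain)


def _tilt_aligned_init(a0: np.ndarray) -> tuple[float, float, float, float]:
    """Initial quaternion mapping the first accelerometer sample to gravity.

    Yaw is set to zero (rotation axis lies in the horizontal plane)."""
    ax, ay, az = float(a0[0]), float(a0[1]), float(a0[2])
    norm = sqrt(ax * ax + ay * ay + az * az)
    if norm < 1e-9:
        return (1.0, 0.0, 0.0, 0.0)
    ax, ay, az = ax / norm, ay / norm, az / norm
    # rotation taking the measured gravity direction onto +z
    vx, vy, vz = ay, -ax, 0.0  # a_hat x e_z
    s = sqrt(vx * vx + vy * vy)
    if s < 1e-12:
        if az > 0:
            return (1.0, 0.0, 0.0, 0.0)
        return (0.0, 1.0, 0.0, 0.0)  # upside down: 180 deg about x
    angle = atan2(s, az)
    ux, uy = vx / s, vy / s
    half = 0.5 * angle
    sh = sin(half)
    return (cos(half), ux * sh, uy * sh, 0.0)


def estimate_orientation(rec: ImuRecording, gain: float = DEFAULT_FILTER_GAIN,
                         drift_gain: float = 0.0,
                         q0: tuple[float, float, float, float] | None = None,
                         ) -> np.ndarray:
    """Estimate one unit quaternion per sample of *rec*.

    Parameters
    ----------
    gain
        Weight of the gradient-descent accelerometer correction (rad/s).
        With ``gain = 0`` the filter reduces to pure gyroscope integration.
    drift_gain
        Integral feedback gain compensating slow gyroscope bias drift from
        the fused gradient error; 0 disables drift correction.
    q0
        Optional initial quaternion (scalar first).  By default the filter
        starts tilt-consistent with the first acceleration sample.

    Returns
    -------
    (n, 4) ndarray of unit quaternions ``[w, x, y, z]``.
    """
    n = len(rec)
    if n == 0:
        raise EmptyInputError("cannot estimate orientation of an empty recording")
    if gain < 0 or drift_gain < 0:
        raise ValueError("gains must be >= 0")
    dt = 1.0 / rec.fs
    a = rec.a
    w = rec.w
    qw, qx, qy, qz = q0 if q0 is not None else _tilt_aligned_init(a[0])
    out = np.empty((n, 4), dtype=float)
    bx = by = bz = 0.0  # integral drift-feedback state, rad/s
    for i in range(n):
        ax = a[i, 0]; ay = a[i, 1]; az = a[i, 2]
        gx = w[i, 0] - bx; gy = w[i, 1] - by; gz = w[i, 2] - bz
        anorm = sqrt(ax * ax + ay * ay + az * az)
        use_acc = gain > 0.0 and anorm > 1e-2
        if use_acc:
            ax /= anorm; ay /= anorm; az /= anorm
            # gravity-direction objective f = R(q)^T e_z - a_hat
            f1 = 2.0 * (qx * qz - qw * qy) - ax
            f2 = 2.0 * (qw * qx + qy * qz) - ay
            f3 = 1.0 - 2.0 * (qx * qx + qy * qy) - az
            g1 = -2.0 * qy * f1 + 2.0 * qx * f2
            g2 = 2.0 * qz * f1 + 2.0 * qw * f2 - 4.0 * qx * f3
            g3 = -2.0 * qw * f1 + 2.0 * qz * f2 - 4.0 * qy * f3
            g4 = 2.0 * qx * f1 + 2.0 * qy * f2
            gnorm = sqrt(g1 * g1 + g2 * g2 + g3 * g3 + g4 * g4)
            if gnorm > 1e-15:
                g1 /= gnorm; g2 /= gnorm; g3 /= gnorm; g4 /= gnorm
                if drift_gain > 0.0:
                    # angular error 2 (q* x grad), integrated into the bias
                    ex = 2.0 * (qw * g2 - qx * g1 - qy * g4 + qz * g3)
                    ey = 2.0 * (qw * g3 + qx * g4 - qy * g1 - qz * g2)
                    ez = 2.0 * (qw * g4 - qx * g3 + qy * g2 - qz * g1)
                    bx += drift_gain * ex * dt
                    by += drift_gain * ey * dt
                    bz += drift_gain * ez * dt
            else:
                use_acc = False
        # first-order quaternion derivative 0.5 q x (0, omega)
        dqw = 0.5 * (-qx * gx - qy * gy - qz * gz)
        dqx = 0.5 * (qw * gx + qy * gz - qz * gy)
        dqy = 0.5 * (qw * gy - qx * gz + qz * gx)
        dqz = 0.5 * (qw * gz + qx * gy - qy * gx)
        if use_acc:
            dqw -= gain * g1
            dqx -= gain * g2
            dqy -= gain * g3
            dqz -= gain * g4
        qw += dqw * dt; qx += dqx * dt; qy += dqy * dt; qz += dqz * dt
        qn = sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw /= qn; qx /= qn; qy /= qn; qz /= qn
        out[i, 0] = qw; out[i, 1] = qx; out[i, 2] = qy; out[i, 3] = qz
    return out


def tilt_from_quaternions(q: np.ndarray) -> np.ndarray:
    """Tilt angle rho in [0, pi] for each quaternion row.

    ``cos(rho)`` is the world-frame z component of the rotated device
    vertical, ``1 - 2 (qx^2 + qy^2)``, clamped to [-1, 1] before arccos.
    """
    q = np.asarray(q, dtype=float)
    c = 1.0 - 2.0 * (q[:, 1] ** 2 + q[:, 2] ** 2)
    return np.arccos(np.clip(c, -1.0, 1.0))


def feature_signals(rec: ImuRecording, q: np.ndarray) -> FeatureSignals:
    """Compute A, W, rho and rho_dot from a recording and its orientation.

    rho_dot uses the central finite difference scaled by the sampling rate
    (one-sided differences at the boundaries).
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (len(rec), 4):
        raise AlignmentError(
            f"quaternion series shape {q.shape} does not match the "
            f"recording length {len(rec)}"
        )
    if len(rec) == 0:
        raise EmptyInputError("empty recording")
    A = np.linalg.norm(rec.a, axis=1)
    W = np.linalg.norm(rec.w, axis=1)
    rho = tilt_from_quaternions(q)
    if len(rho) >= 2:
        rho_dot = np.gradient(rho, 1.0 / rec.fs)
    else:
        rho_dot = np.zeros_like(rho)
    return FeatureSignals(A=A, W=W, rho=rho, rho_dot=rho_dot, fs=rec.fs)


def compute_features(rec: ImuRecording, gain: float = DEFAULT_FILTER_GAIN,
                     drift_gain: float = 0.0) -> FeatureSignals:
    """Convenience: orientation estimation followed by feature extraction."""
    q = estimate_orientation(rec, gain=gain, drift_gain=drift_gain)
    return feature_signals(rec, q)
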