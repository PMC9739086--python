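"""Gradient-descent (Madgwick) orientation filter with warm-up handling.

One filter step blends two information sources: the gyroscope propagates the
orientation through the quaternion rate equation ``q̇ = ½ q ⊗ (0, ω)``, and
the accelerometer + magnetometer define an objective function whose value is
zero when the predicted earth-frame gravity and magnetic-field directions
match the (normalized) measurements.  The orientation is corrected along the
negative normalized gradient of that objective, scaled by the gain ``beta``,
then re-normalized:

    q ← normalize( q + (½ q ⊗ (0, ω) − β ∇F/‖∇F‖) · Δt )

``beta`` trades gyro trust against accel/mag trust: it is the magnitude (in
rad/s) of the orientation correction applied per unit time, so it bounds how
fast gyro bias can be absorbed and how hard dynamic (non-gravity)
acceleration can corrupt the attitude.

Conventions
-----------
All sensor axes follow NED (X north, Y east, Z down).  Gravity is ``+g``
along Down, so a stationary accelerometer reads specific force ``(0, 0, −g)``
and the earth-frame gravity reference used in the objective is the unit
vector ``(0, 0, −1)``.  The magnetic-field reference is re-derived each step
from the measurement itself as a horizontal-plus-vertical NED decomposition
``(b_x, 0, b_z)``, which makes the filter immune to a wrong assumed
declination.  The filter state is the attitude (body→earth); the emitted
:class:`OrientationTrack` stores the conjugate (earth→body), the quaternion
whose rotation-matrix *inverse* maps body accelerations to the earth frame
(see :mod:`wristkin.quaternion`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .quaternion import (
    IDENTITY,
    quat_conjugate,
    quat_normalize,
    quat_to_euler,
)

if TYPE_CHECKING:  # pragma: no cover
    from .kinematics import ImuCapture

__all__ = [
    "FusionConfig",
    "OrientationTrack",
    "StabilizationResult",
    "madgwick_update",
    "stabilize",
    "fuse_capture",
]

logger = logging.getLogger(__name__)

# Earth-frame direction of the specific force measured at rest (NED: up).
_GRAVITY_REF = np.array([0.0, 0.0, -1.0])

# Default earth magnetic field direction: mid-latitude ~60° inclination,
# horizontal component along north.
_DEFAULT_MAG_REF = np.array([np.cos(np.radians(60.0)), 0.0,
                             np.sin(np.radians(60.0))])


@dataclass
class FusionConfig:
    """Parameters of the orientation filter.

    beta
        Filter gain (rad/s of correction authority), > 0 for fusion; 0 makes
        the filter pure gyro integration.  The default 0.041 is the gain the
        filter's original publication recommends for 9-DoF (MARG) operation;
        larger gains absorb gyro bias faster but let sustained dynamic
        acceleration (e.g. the ~1 g centripetal load of an arm swing) tilt
        the attitude harder.
    sample_period
        Capture clock period in seconds (0.002 s for the default capture).
    magnetic_reference
        Unit earth-frame field direction (NED horizontal + vertical); used by
        the synthetic generator and as documentation of the assumed field.
    initial_orientation
        Starting track quaternion (earth→body); identity by default — the
        warm-up phase is what absorbs initialization error.
    warmup_seconds
        Stabilization time before a capture is trusted.
    """

    beta: float = 0.041
    sample_period: float = 0.002
    magnetic_reference: np.ndarray = field(
        default_factory=lambda: _DEFAULT_MAG_REF.copy())
    initial_orientation: np.ndarray = field(
        default_factory=lambda: IDENTITY.copy())
    warmup_seconds: float = 20.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be > 0")
        ref = np.asarray(self.magnetic_reference, dtype=float)
        n = float(np.linalg.norm(ref))
        if ref.shape != (3,) or n == 0.0:
            raise ValueError("magnetic_reference must be a nonzero 3-vector")
        self.magnetic_reference = ref / n
        self.initial_orientation = quat_normalize(self.initial_orientation)


@dataclass
class OrientationTrack:
    """Per-sample orientation quaternions aligned with a capture.

    ``quaternions[i]`` is the earth→body quaternion for sample ``i`` (the one
    :func:`wristkin.quaternion.rotate_body_to_earth` expects); ``t`` carries
    the aligned timestamps.
    """

    t: np.ndarray
    quaternions: np.ndarray  # (n, 4), earth→body

    def __len__(self) -> int:
        return len(self.quaternions)

    def attitude_euler(self) -> np.ndarray:
        """(n, 3) yaw/pitch/roll in degrees of the body→earth attitude."""
        return np.array([quat_to_euler(quat_conjugate(q))
                         for q in self.quaternions])


@dataclass
class StabilizationResult:
    orientation: np.ndarray       # earth→body track quaternion after warm-up
    euler_history: np.ndarray     # (n, 3) attitude yaw/pitch/roll, degrees
    converged: bool


def _objective_and_jacobian(q: np.ndarray, acc_n: np.ndarray,
                            mag_n: np.ndarray | None):
    """Objective f(q) and Jacobian J for the gradient step.

    ``q`` is the attitude (body→earth); the model predicts each normalized
    body-frame measurement as ``R(q)ᵀ d`` for earth reference ``d``:
    ``d_g = (0,0,−1)`` for gravity and ``d_b = (b_x, 0, b_z)`` for the
    magnetic field, with ``b`` recovered from the measurement itself.
    """
    q0, q1, q2, q3 = q
    ax, ay, az = acc_n
    f_g = np.array([
        -(2 * q1 * q3 - 2 * q0 * q2) - ax,
        -(2 * q2 * q3 + 2 * q0 * q1) - ay,
        -(q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3) - az,
    ])
    J_g = np.array([
        [2 * q2, -2 * q3, 2 * q0, -2 * q1],
        [-2 * q1, -2 * q0, -2 * q3, -2 * q2],
        [-2 * q0, 2 * q1, 2 * q2, -2 * q3],
    ])
    if mag_n is None:
        return f_g, J_g

    mx, my, mz = mag_n
    # Earth-frame field from the measurement, decomposed as (bx, 0, bz).
    hx = mx * (q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3) \
        + my * (2 * q1 * q2 - 2 * q0 * q3) + mz * (2 * q1 * q3 + 2 * q0 * q2)
    hy = mx * (2 * q1 * q2 + 2 * q0 * q3) \
        + my * (q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3) \
        + mz * (2 * q2 * q3 - 2 * q0 * q1)
    hz = mx * (2 * q1 * q3 - 2 * q0 * q2) + my * (2 * q2 * q3 + 2 * q0 * q1) \
        + mz * (q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3)
    bx = np.hypot(hx, hy)
    bz = hz

    f_b = np.array([
        bx * (q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3)
        + bz * (2 * q1 * q3 - 2 * q0 * q2) - mx,
        bx * (2 * q1 * q2 - 2 * q0 * q3)
        + bz * (2 * q2 * q3 + 2 * q0 * q1) - my,
        bx * (2 * q1 * q3 + 2 * q0 * q2)
        + bz * (q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3) - mz,
    ])
    J_b = np.array([
        [2 * bx * q0 - 2 * bz * q2, 2 * bx * q1 + 2 * bz * q3,
         -2 * bx * q2 - 2 * bz * q0, -2 * bx * q3 + 2 * bz * q1],
        [-2 * bx * q3 + 2 * bz * q1, 2 * bx * q2 + 2 * bz * q0,
         2 * bx * q1 + 2 * bz * q3, -2 * bx * q0 + 2 * bz * q2],
        [2 * bx * q2 + 2 * bz * q0, 2 * bx * q3 - 2 * bz * q1,
         2 * bx * q0 - 2 * bz * q3, 2 * bx * q1 + 2 * bz * q2],
    ])
    return np.concatenate([f_g, f_b]), np.vstack([J_g, J_b])


def _attitude_rate(q: np.ndarray, gyro: np.ndarray) -> np.ndarray:
    """½ q ⊗ (0, ω) without normalization (a rate, not a rotation)."""
    q0, q1, q2, q3 = q
    gx, gy, gz = gyro
    return 0.5 * np.array([
        -q1 * gx - q2 * gy - q3 * gz,
        q0 * gx + q2 * gz - q3 * gy,
        q0 * gy - q1 * gz + q3 * gx,
        q0 * gz + q1 * gy - q2 * gx,
    ])


def _update_attitude(q: np.ndarray, gyro: np.ndarray, accel: np.ndarray,
                     mag: np.ndarray | None, beta: float,
                     dt: float) -> np.ndarray:
    """One filter step on the internal attitude (body→earth) state."""
    qdot = _attitude_rate(q, gyro)
    a_norm = float(np.linalg.norm(accel))
    if beta > 0.0 and a_norm > 0.0:
        acc_n = accel / a_norm
        if mag is not None:
            m_norm = float(np.linalg.norm(mag))
            mag_n = mag / m_norm if m_norm > 0.0 else None
        else:
            mag_n = None
        f, J = _objective_and_jacobian(q, acc_n, mag_n)
        grad = J.T @ f
        g_norm = float(np.linalg.norm(grad))
        if g_norm > 0.0:
            qdot = qdot - beta * grad / g_norm
    elif beta > 0.0:
        logger.warning("zero accelerometer vector: gyro-only propagation "
                       "for this step")
    return quat_normalize(q + qdot * dt)


def madgwick_update(q_prev, gyro, accel, mag, cfg: FusionConfig) -> np.ndarray:
    """One fusion step; all quantities in the track convention.

    Parameters
    ----------
    q_prev : (4,) array
        Previous earth→body quaternion (unit norm).
    gyro : (3,) array, rad/s
    accel : (3,) array, m/s² (specific force, NED body axes)
    mag : (3,) array, gauss, or None for accel+gyro-only fusion
    """
    q_prev = quat_normalize(np.asarray(q_prev, float))
    attitude = quat_conjugate(q_prev)
    attitude = _update_attitude(
        attitude, np.asarray(gyro, float), np.asarray(accel, float),
        None if mag is None else np.asarray(mag, float),
        cfg.beta, cfg.sample_period)
    return quat_conjugate(attitude)


def _run_filter(capture: "ImuCapture", cfg: FusionConfig) -> np.ndarray:
    """Vector of attitude quaternions (n, 4) over a capture."""
    n = capture.n_samples
    dt = capture.sample_period
    attitude = quat_conjugate(cfg.initial_orientation)
    out = np.empty((n, 4))
    gyro, accel, mag = capture.gyro_xyz, capture.accel_xyz, capture.mag_xyz
    for i in range(n):
        attitude = _update_attitude(attitude, gyro[i], accel[i],
                                    None if mag is None else mag[i],
                                    cfg.beta, dt)
        out[i] = attitude
    return out


def fuse_capture(capture: "ImuCapture", cfg: FusionConfig) -> OrientationTrack:
    """Run the filter over a whole capture; one quaternion per sample."""
    attitudes = _run_filter(capture, cfg)
    quats = attitudes * np.array([1.0, -1.0, -1.0, -1.0])  # conjugate
    return OrientationTrack(t=capture.t, quaternions=quats)


def stabilize(capture_head: "ImuCapture",
              cfg: FusionConfig) -> StabilizationResult:
    """Warm-up phase: run the filter until the orientation settles.

    The capture head must cover at least ``cfg.warmup_seconds``.  Convergence
    is declared when, over the last second, yaw, pitch and roll each vary by
    less than 0.5°.
    """
    dt = capture_head.sample_period
    required = int(round(cfg.warmup_seconds / dt))
    if required < 1 or capture_head.n_samples < required:
        raise ValueError(
            f"warm-up needs at least {max(required, 1)} samples "
            f"({cfg.warmup_seconds} s at {dt} s/sample); "
            f"got {capture_head.n_samples}")
    attitudes = _run_filter(capture_head, cfg)
    euler = np.array([quat_to_euler(q) for q in attitudes])
    fs = int(round(1.0 / dt))
    tail = np.unwrap(np.radians(euler[-max(fs, 2):]), axis=0)
    spans = np.degrees(tail.max(axis=0) - tail.min(axis=0))
    converged = bool(np.all(spans < 0.5))
    return StabilizationResult(
        orientation=quat_conjugate(attitudes[-1]),
        euler_history=euler,
        converged=converged,
    )
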