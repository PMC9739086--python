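"""Quaternion algebra and body/earth rotation.

Orientation is represented everywhere as a unit quaternion ``(q0, q1, q2, q3)``
with scalar part first and Hamilton convention (``i·j = k``).  A quaternion is
stored as a plain ``numpy`` array of shape ``(4,)``; functions in this module
are the only orientation math used downstream.

Frame convention
----------------
The package works in the aerospace north-east-down (NED) frame: X north,
Y east, Z toward the Earth's centre.  The rotation matrix ``R(q)`` returned by
:func:`quat_to_rotation_matrix` is the classic homogeneous expression of the
rotation encoded by ``q``.  For an orientation track produced by the fusion
filter the stored quaternion maps *earth*-frame vectors into the *body* frame,
so device accelerations are brought into the earth frame by multiplying with
the **inverse** (transpose) of ``R(q)`` — exactly what
:func:`rotate_body_to_earth` does.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "quat_normalize",
    "quat_from_axis_angle",
    "quat_multiply",
    "quat_conjugate",
    "quat_to_rotation_matrix",
    "rotate_body_to_earth",
    "quat_to_euler",
    "quat_from_euler",
    "quat_angle_between",
    "is_gimbal_degenerate",
]

#: The identity rotation.
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

_UNIT_TOL = 1e-6


def _as_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"quaternion must have shape (4,), got {q.shape}")
    return q


def _require_unit(q: np.ndarray, tol: float = _UNIT_TOL) -> np.ndarray:
    n = float(np.linalg.norm(q))
    if abs(n - 1.0) > tol:
        raise ValueError(f"quaternion is not unit-norm: |q| = {n!r}")
    return q


def quat_normalize(q) -> np.ndarray:
    """Scale ``q`` to unit norm.  Rejects the zero quaternion."""
    q = _as_quat(q)
    n = float(np.linalg.norm(q))
    if n == 0.0:
        raise ValueError("cannot normalize the zero quaternion")
    return q / n


def quat_from_axis_angle(axis, angle: float) -> np.ndarray:
    """Quaternion for a rotation of ``angle`` radians about the unit ``axis``.

    Returns ``(cos(angle/2), axis * sin(angle/2))``.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (3,):
        raise ValueError(f"axis must have shape (3,), got {axis.shape}")
    n = float(np.linalg.norm(axis))
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"axis must be a unit vector: |axis| = {n!r}")
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    half = 0.5 * angle
    return quat_normalize(np.concatenate(([np.cos(half)], axis * np.sin(half))))


def quat_multiply(q_second, q_first) -> np.ndarray:
    """Hamilton product ``q_second ⊗ q_first``.

    Composition order is "apply ``q_first``, then ``q_second``": the product
    encodes the rotation obtained by rotating first according to ``q_first``
    and subsequently according to ``q_second``.  The result is re-normalized
    to guard against drift in long chains (the fusion filter composes
    thousands of these per capture).
    """
    a = _require_unit(_as_quat(q_second))
    b = _require_unit(_as_quat(q_first))
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    out = np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])
    return quat_normalize(out)


def quat_conjugate(q) -> np.ndarray:
    """Conjugate ``(q0, −q1, −q2, −q3)``; the inverse for unit quaternions."""
    q = _as_quat(q)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_to_rotation_matrix(q) -> np.ndarray:
    """The 3×3 rotation matrix of ``q`` in homogeneous quadratic form.

    ``R`` is orthonormal with determinant +1; ``q`` and ``−q`` map to the
    same matrix.
    """
    q = _require_unit(_as_quat(q))
    q0, q1, q2, q3 = q
    return np.array([
        [q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
         2 * q1 * q2 - 2 * q0 * q3,
         2 * q1 * q3 + 2 * q0 * q2],
        [2 * q1 * q2 + 2 * q0 * q3,
         q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
         2 * q2 * q3 - 2 * q0 * q1],
        [2 * q1 * q3 - 2 * q0 * q2,
         2 * q2 * q3 + 2 * q0 * q1,
         q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3],
    ])


def rotate_body_to_earth(q, v_body) -> np.ndarray:
    """Map a body-frame vector into the earth (NED) frame.

    ``q`` is the orientation-track quaternion (earth→body); the earth-frame
    vector is ``R(q)⁻¹ · v_body = R(q)ᵀ · v_body``.  Rotations are isometries,
    so the norm of the input is preserved.

    ``v_body`` may be a single 3-vector or an ``(n, 3)`` array of vectors
    (all rotated by the same ``q``).
    """
    R = quat_to_rotation_matrix(q)  # validates unit norm
    v = np.asarray(v_body, dtype=float)
    return v @ R  # (R.T @ v.T).T


def quat_to_euler(q, degrees: bool = True):
    """Aerospace ZYX (yaw-pitch-roll) Euler angles of the rotation ``q``.

    ``q`` is interpreted as the attitude (body→earth active rotation); yaw is
    the heading about NED Down, pitch the elevation, roll the bank.  Used only
    for display (the stabilization plot); the kinematics never touch Euler
    angles, precisely to stay clear of gimbal lock.

    Within 1e−9 of pitch = ±90° the decomposition is degenerate (yaw and roll
    are not unique); :func:`is_gimbal_degenerate` flags this, and here the
    returned yaw absorbs the full azimuthal rotation with roll set to 0.
    """
    q = _require_unit(_as_quat(q))
    R = quat_to_rotation_matrix(q)
    s = -R[2, 0]  # sin(pitch)
    s = float(np.clip(s, -1.0, 1.0))
    pitch = np.arcsin(s)
    if abs(abs(s) - 1.0) <= 1e-9:
        # gimbal-degenerate: only yaw ± roll is observable
        yaw = np.arctan2(-R[0, 1], R[1, 1])
        roll = 0.0
    else:
        yaw = np.arctan2(R[1, 0], R[0, 0])
        roll = np.arctan2(R[2, 1], R[2, 2])
    out = np.array([yaw, pitch, roll])
    return np.degrees(out) if degrees else out


def is_gimbal_degenerate(q, tol: float = 1e-9) -> bool:
    """True when pitch is within ``tol`` (on sin(pitch)) of ±90°."""
    q = _require_unit(_as_quat(q))
    R = quat_to_rotation_matrix(q)
    return bool(abs(abs(R[2, 0]) - 1.0) <= tol)


def quat_from_euler(yaw: float, pitch: float, roll: float,
                    degrees: bool = True) -> np.ndarray:
    """Attitude quaternion from aerospace ZYX yaw-pitch-roll angles."""
    if degrees:
        yaw, pitch, roll = np.radians([yaw, pitch, roll])
    qz = quat_from_axis_angle(np.array([0.0, 0.0, 1.0]), yaw)
    qy = quat_from_axis_angle(np.array([0.0, 1.0, 0.0]), pitch)
    qx = quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), roll)
    return quat_multiply(quat_multiply(qz, qy), qx)


def quat_angle_between(qa, qb) -> float:
    """Rotation angle (radians) taking ``qa`` to ``qb``; double-cover safe."""
    qa = _require_unit(_as_quat(qa))
    qb = _require_unit(_as_quat(qb))
    d = quat_multiply(quat_conjugate(qa), qb)
    return 2.0 * float(np.arccos(np.clip(abs(d[0]), -1.0, 1.0)))
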