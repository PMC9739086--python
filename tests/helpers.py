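"""Independent reference implementations used as test oracles.

Everything here is deliberately written down a *different* route from the
package code it checks: rotations go through scipy, gradients are obtained
by finite differences rather than an analytic Jacobian, and the ZUPT scan is
a naive O(n·count) window sweep.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

GRAVITY_DIR = np.array([0.0, 0.0, -1.0])  # NED specific-force direction


def scipy_matrix(q_scalar_first):
    """Rotation matrix of a scalar-first quaternion via scipy (oracle route)."""
    w, x, y, z = q_scalar_first
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def rodrigues_rotate(axis, angle, v):
    """Rodrigues' rotation formula, the textbook closed form."""
    axis = np.asarray(axis, float)
    v = np.asarray(v, float)
    k = axis / np.linalg.norm(axis)
    return (v * np.cos(angle) + np.cross(k, v) * np.sin(angle)
            + k * np.dot(k, v) * (1.0 - np.cos(angle)))


# ---------------------------------------------------------------------------
# numerical-gradient reference of the gradient-descent orientation filter
# ---------------------------------------------------------------------------

def _hprod(a, b):
    """Hamilton product, scalar-first (local to the oracle)."""
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _objective(q, acc_n, mag_n):
    """Stacked measurement residual f(q); rotations via scipy."""
    Rt = scipy_matrix(q / np.linalg.norm(q)).T
    parts = [Rt @ GRAVITY_DIR - acc_n]
    if mag_n is not None:
        h = scipy_matrix(q / np.linalg.norm(q)) @ mag_n
        b = np.array([np.hypot(h[0], h[1]), 0.0, h[2]])
        parts.append(Rt @ b - mag_n)
    return np.concatenate(parts)


def reference_update(q_att, gyro, accel, mag, beta, dt, eps=1e-6):
    """One filter step on the attitude, with a finite-difference gradient.

    The correction direction is the gradient of ½‖f(q)‖², estimated by
    central differences — no analytic Jacobian is involved.
    """
    acc_n = accel / np.linalg.norm(accel)
    mag_n = None
    if mag is not None:
        mn = np.linalg.norm(mag)
        mag_n = mag / mn if mn > 0 else None
    grad = np.empty(4)
    for i in range(4):
        qp, qm = q_att.copy(), q_att.copy()
        qp[i] += eps
        qm[i] -= eps
        fp = _objective(qp, acc_n, mag_n)
        fm = _objective(qm, acc_n, mag_n)
        grad[i] = (0.5 * fp @ fp - 0.5 * fm @ fm) / (2.0 * eps)
    gnorm = np.linalg.norm(grad)
    qdot = 0.5 * _hprod(q_att, np.concatenate(([0.0], gyro)))
    if gnorm > 0:
        qdot = qdot - beta * grad / gnorm
    q = q_att + qdot * dt
    return q / np.linalg.norm(q)


def reference_fuse(capture, beta, q0_att=None):
    """Run the reference filter over a capture; returns final attitude."""
    q = np.array([1.0, 0.0, 0.0, 0.0]) if q0_att is None else q0_att.copy()
    for i in range(capture.n_samples):
        q = reference_update(q, capture.gyro_xyz[i], capture.accel_xyz[i],
                             capture.mag_xyz[i], beta, capture.sample_period)
    return q


# ---------------------------------------------------------------------------
# naive ZUPT oracle
# ---------------------------------------------------------------------------

def zupt_bruteforce(dyn_accel, velocity, limit, count):
    """O(n·count) sliding-window scan: zero every sample covered by a
    fully-quiet window of length ``count``."""
    a = np.atleast_2d(np.asarray(dyn_accel, float))
    v = np.atleast_2d(np.asarray(velocity, float)).copy()
    n = len(a)
    quiet = np.all(np.abs(a) < limit, axis=1)
    zero = np.zeros(n, dtype=bool)
    for s in range(0, n - count + 1):
        if quiet[s:s + count].all():
            zero[s:s + count] = True
    v[zero] = 0.0
    return v, zero
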