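"""Synthetic ground-truth trajectories and the 9-DoF streams they imply.

This module stands in for the physical capture device: it builds parametric
wrist trajectories (position + orientation vs time), samples them at the
capture rate, and runs the *forward* sensor model — the exact inverse of the
processing chain — to produce the accelerometer / gyroscope / magnetometer
streams a wrist-worn IMU would record, with optional noise and bias.  The
whole pipeline is thereby testable at desk scale: reconstruction can be
compared against known truth.

Forward model (NED, gravity +g along Down):

* accelerometer: specific force ``R(q)ᵀ (a_earth − g_vec)`` in body axes,
  plus bias and white noise;
* gyroscope: body angular rate ``ω = 2 vec(q* ⊗ q̇)`` plus constant bias, a
  slow bias ramp, and white noise;
* magnetometer: the earth field rotated into the body frame, sampled and
  held at its own 40 Hz output data rate on the 500 Hz capture clock (what a
  polling loop on the device would read), plus white noise per field update.

The discus preset mimics an amateur discus throw as seen by the wrist: a
stationary hold, a reverse half-arc wind-up, a forward accelerating turn,
and a fast release arc reaching the release speed, each separated by
near-zero-speed instants — giving the characteristic three-peak speed
profile with its global maximum at release.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fusion import _DEFAULT_MAG_REF
from .kinematics import STANDARD_GRAVITY, ImuCapture
from .quaternion import quat_from_axis_angle, quat_to_rotation_matrix

__all__ = [
    "TrajectorySpec",
    "GroundTruth",
    "NoiseModel",
    "simulate_truth",
    "truth_to_imu",
    "stationary_preset",
    "out_and_back_preset",
    "circle_preset",
    "discus_throw_preset",
    "PRESETS",
    "make_preset",
]

MAG_ODR_HZ = 40.0             # magnetometer output data rate
EARTH_FIELD_GAUSS = 0.45      # default field magnitude
GYRO_FULL_SCALE_RAD = np.radians(2000.0)  # ±2000 dps


@dataclass
class TrajectorySpec:
    """Parametric ground-truth motion on ``[0, duration]``.

    ``position(t)`` returns earth-frame meters (NED); ``attitude(t)`` the
    body→earth unit quaternion.  Analytic derivative callables are optional;
    when absent, :func:`simulate_truth` falls back to central differences.
    """

    name: str
    duration: float
    position: Callable[[float], np.ndarray]
    attitude: Callable[[float], np.ndarray]
    velocity: Callable[[float], np.ndarray] | None = None
    acceleration: Callable[[float], np.ndarray] | None = None
    angular_rate: Callable[[float], np.ndarray] | None = None  # body rad/s


@dataclass
class GroundTruth:
    """Sampled truth: aligned kinematics + orientation arrays."""

    t: np.ndarray
    sample_period: float
    position: np.ndarray      # (n, 3) m
    velocity: np.ndarray      # (n, 3) m/s
    acceleration: np.ndarray  # (n, 3) m/s²
    attitude: np.ndarray      # (n, 4) body→earth quaternions
    angular_rate: np.ndarray  # (n, 3) body rad/s

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class NoiseModel:
    """Sensor imperfections; all randomness flows from ``seed``.

    Defaults are plausible for a consumer MEMS IMU of this class:
    accelerometer white noise 0.05 m/s², gyro white noise 0.2 deg/s with a
    constant 0.5 deg/s bias and a 0.01 deg/s per second slow ramp,
    magnetometer white noise 0.005 gauss.
    """

    accel_sigma: float = 0.05                     # m/s²
    gyro_sigma: float = np.radians(0.2)           # rad/s
    mag_sigma: float = 0.005                      # gauss
    accel_bias: np.ndarray = field(
        default_factory=lambda: np.zeros(3))      # m/s²
    gyro_bias: np.ndarray = field(
        default_factory=lambda: np.full(3, np.radians(0.5)))  # rad/s
    gyro_drift_rate: float = np.radians(0.01)     # rad/s per second
    seed: int = 0

    def __post_init__(self) -> None:
        self.accel_bias = np.asarray(self.accel_bias, float).reshape(3)
        self.gyro_bias = np.asarray(self.gyro_bias, float).reshape(3)
        for s in (self.accel_sigma, self.gyro_sigma, self.mag_sigma):
            if s < 0:
                raise ValueError("noise standard deviations must be >= 0")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        """Noise-free, bias-free model (for inversion tests)."""
        return cls(accel_sigma=0.0, gyro_sigma=0.0, mag_sigma=0.0,
                   accel_bias=np.zeros(3), gyro_bias=np.zeros(3),
                   gyro_drift_rate=0.0, seed=seed)


# ---------------------------------------------------------------------------
# sampling the truth
# ---------------------------------------------------------------------------

def _sample_vec(fn, t: np.ndarray, width: int) -> np.ndarray:
    out = np.empty((len(t), width))
    for i, ti in enumerate(t):
        v = np.asarray(fn(float(ti)), float)
        if v.shape != (width,):
            raise ValueError(f"path callable returned shape {v.shape}, "
                             f"expected ({width},)")
        out[i] = v
    return out


def _align_hemispheres(q: np.ndarray) -> np.ndarray:
    """Flip signs so consecutive quaternions sit in the same hemisphere."""
    q = q.copy()
    for i in range(1, len(q)):
        if np.dot(q[i], q[i - 1]) < 0:
            q[i] = -q[i]
    return q


def _angular_rate_from_quats(q: np.ndarray, dt: float) -> np.ndarray:
    """Body angular rate ``2 vec(q* ⊗ q̇)`` by central differences."""
    qdot = np.gradient(q, dt, axis=0)
    w, x, y, z = q.T
    dw, dx, dy, dz = qdot.T
    # vector part of conj(q) ⊗ qdot
    ox = w * dx - x * dw - y * dz + z * dy
    oy = w * dy + x * dz - y * dw - z * dx
    oz = w * dz - x * dy + y * dx - z * dw
    return 2.0 * np.column_stack([ox, oy, oz])


def simulate_truth(spec: TrajectorySpec, fs: float) -> GroundTruth:
    """Sample a trajectory at ``fs`` Hz; differentiate where needed."""
    if fs <= 0:
        raise ValueError("fs must be > 0")
    n = int(round(spec.duration * fs))
    if n < 2:
        raise ValueError("duration · fs must be at least 2 samples")
    dt = 1.0 / fs
    t = np.arange(n) * dt

    pos = _sample_vec(spec.position, t, 3)
    if not np.all(np.isfinite(pos)):
        raise ValueError("position path produced non-finite values")

    vel = (_sample_vec(spec.velocity, t, 3) if spec.velocity is not None
           else np.gradient(pos, dt, axis=0))
    acc = (_sample_vec(spec.acceleration, t, 3)
           if spec.acceleration is not None
           else np.gradient(vel, dt, axis=0))

    att = _align_hemispheres(_sample_vec(spec.attitude, t, 4))
    att /= np.linalg.norm(att, axis=1, keepdims=True)
    omega = (_sample_vec(spec.angular_rate, t, 3)
             if spec.angular_rate is not None
             else _angular_rate_from_quats(att, dt))

    return GroundTruth(t=t, sample_period=dt, position=pos, velocity=vel,
                       acceleration=acc, attitude=att, angular_rate=omega)


# ---------------------------------------------------------------------------
# forward sensor model
# ---------------------------------------------------------------------------

def truth_to_imu(truth: GroundTruth, noise: NoiseModel | None = None,
                 g: float = STANDARD_GRAVITY,
                 magnetic_reference: np.ndarray | None = None,
                 field_gauss: float = EARTH_FIELD_GAUSS) -> ImuCapture:
    """Run the forward sensor model: truth → noisy 9-DoF capture."""
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    n = len(truth)
    dt = truth.sample_period

    ref = (_DEFAULT_MAG_REF if magnetic_reference is None
           else np.asarray(magnetic_reference, float))
    ref = ref / np.linalg.norm(ref)
    b_earth = field_gauss * ref
    g_vec = np.array([0.0, 0.0, g])

    accel = np.empty((n, 3))
    mag_clean = np.empty((n, 3))
    for i in range(n):
        R = quat_to_rotation_matrix(truth.attitude[i])  # body→earth
        accel[i] = R.T @ (truth.acceleration[i] - g_vec)
        mag_clean[i] = R.T @ b_earth
    accel += noise.accel_bias
    accel += rng.normal(0.0, noise.accel_sigma, (n, 3))

    gyro = truth.angular_rate + noise.gyro_bias \
        + noise.gyro_drift_rate * truth.t[:, None] \
        + rng.normal(0.0, noise.gyro_sigma, (n, 3))

    # magnetometer: sample-and-hold at its own ODR on the capture clock,
    # with one noise draw per field update (held values repeat verbatim)
    update_idx = np.searchsorted(truth.t, np.floor(truth.t * MAG_ODR_HZ)
                                 / MAG_ODR_HZ, side="left")
    update_idx = np.clip(update_idx, 0, n - 1)
    uniq, inverse = np.unique(update_idx, return_inverse=True)
    mag_updates = mag_clean[uniq] + rng.normal(0.0, noise.mag_sigma,
                                               (len(uniq), 3))
    mag = mag_updates[inverse]

    return ImuCapture(sample_period=dt, accel_xyz=accel, gyro_xyz=gyro,
                      mag_xyz=mag)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_Z_AXIS = np.array([0.0, 0.0, 1.0])
_IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


class _Bump:
    """A smooth sin² velocity bump on [start, start+width].

    value   = A · sin²(π (t−start)/width)       (zero outside)
    integral(t) = closed-form running integral   (A·width/2 in total)
    slope   = analytic derivative of value
    """

    def __init__(self, amplitude: float, start: float, width: float):
        self.A, self.s, self.d = amplitude, start, width

    def value(self, t: float) -> float:
        u = t - self.s
        if u <= 0.0 or u >= self.d:
            return 0.0
        return self.A * np.sin(np.pi * u / self.d) ** 2

    def slope(self, t: float) -> float:
        u = t - self.s
        if u <= 0.0 or u >= self.d:
            return 0.0
        return self.A * np.pi / self.d * np.sin(2.0 * np.pi * u / self.d)

    def integral(self, t: float) -> float:
        u = np.clip(t - self.s, 0.0, self.d)
        return self.A * (u / 2.0
                         - self.d / (4.0 * np.pi)
                         * np.sin(2.0 * np.pi * u / self.d))

    @property
    def total(self) -> float:
        return self.A * self.d / 2.0


def stationary_preset(duration: float = 6.0) -> TrajectorySpec:
    """Device at rest at the origin, identity attitude."""
    zero3 = np.zeros(3)
    return TrajectorySpec(
        name="stationary", duration=duration,
        position=lambda t: zero3, attitude=lambda t: _IDENTITY_Q,
        velocity=lambda t: zero3, acceleration=lambda t: zero3,
        angular_rate=lambda t: zero3)


def out_and_back_preset(distance: float = 1.0, duration: float = 6.0,
                        hold: float = 1.0) -> TrajectorySpec:
    """Smooth straight-line excursion along north and return to the origin.

    Rest for ``hold`` s, glide out to ``distance`` m and back with a
    raised-cosine profile, rest again.
    """
    move = duration - 2.0 * hold
    if move <= 0:
        raise ValueError("duration must exceed twice the hold time")

    def s_of(t: float) -> float:  # displacement profile, 0→0
        u = (t - hold) / move
        if u <= 0.0 or u >= 1.0:
            return 0.0
        return distance * np.sin(np.pi * u) ** 2

    def ds_of(t: float) -> float:
        u = (t - hold) / move
        if u <= 0.0 or u >= 1.0:
            return 0.0
        return distance * np.pi / move * np.sin(2.0 * np.pi * u)

    def dds_of(t: float) -> float:
        u = (t - hold) / move
        if u <= 0.0 or u >= 1.0:
            return 0.0
        return distance * 2.0 * (np.pi / move) ** 2 * np.cos(2.0 * np.pi * u)

    return TrajectorySpec(
        name="out_and_back", duration=duration,
        position=lambda t: np.array([s_of(t), 0.0, 0.0]),
        velocity=lambda t: np.array([ds_of(t), 0.0, 0.0]),
        acceleration=lambda t: np.array([dds_of(t), 0.0, 0.0]),
        attitude=lambda t: _IDENTITY_Q,
        angular_rate=lambda t: np.zeros(3))


def circle_preset(radius: float = 1.0, period: float = 2.0,
                  duration: float = 6.0, hold: float = 0.5,
                  spin_up: float = 1.0) -> TrajectorySpec:
    """Horizontal circle: rest, smooth spin-up, then uniform circular motion.

    The device translates around the circle without rotating (identity
    attitude), so the gyroscope stays quiet and the accelerometer carries the
    centripetal signal.
    """
    if radius <= 0 or period <= 0:
        raise ValueError("radius and period must be > 0")
    omega = 2.0 * np.pi / period
    theta_end_rampup = omega * 0.5 * spin_up  # angle covered by spin-up

    def theta_rate(t: float) -> float:
        u = t - hold
        if u <= 0.0:
            return 0.0
        if u >= spin_up:
            return omega
        return omega * 0.5 * (1.0 - np.cos(np.pi * u / spin_up))

    def theta_acc(t: float) -> float:
        u = t - hold
        if u <= 0.0 or u >= spin_up:
            return 0.0
        return omega * 0.5 * np.pi / spin_up * np.sin(np.pi * u / spin_up)

    def theta(t: float) -> float:
        u = t - hold
        if u <= 0.0:
            return 0.0
        if u <= spin_up:
            return omega * 0.5 * (u - spin_up / np.pi
                                  * np.sin(np.pi * u / spin_up))
        return theta_end_rampup + omega * (u - spin_up)

    def position(t: float) -> np.ndarray:
        th = theta(t)
        return np.array([radius * np.sin(th),
                         radius * (1.0 - np.cos(th)), 0.0])

    def velocity(t: float) -> np.ndarray:
        th, thd = theta(t), theta_rate(t)
        return np.array([radius * thd * np.cos(th),
                         radius * thd * np.sin(th), 0.0])

    def acceleration(t: float) -> np.ndarray:
        th, thd, thdd = theta(t), theta_rate(t), theta_acc(t)
        return np.array([
            radius * (thdd * np.cos(th) - thd * thd * np.sin(th)),
            radius * (thdd * np.sin(th) + thd * thd * np.cos(th)), 0.0])

    return TrajectorySpec(
        name="circle", duration=duration,
        position=position, velocity=velocity, acceleration=acceleration,
        attitude=lambda t: _IDENTITY_Q, angular_rate=lambda t: np.zeros(3))


def discus_throw_preset(radius: float = 0.9, windup_fraction: float = 0.5,
                        release_speed: float = 15.0,
                        duration: float = 6.0) -> TrajectorySpec:
    """A discus-throw-like wrist trajectory over a 6 s capture.

    Phases: stationary hold → reverse half-arc wind-up (``windup_fraction``
    of a full circle, opposite sense) → forward accelerating turn → fast
    release arc peaking at ``release_speed`` → rest.  The ground-truth speed
    profile has three local maxima (two when ``windup_fraction`` is 0) with
    the global maximum inside the release segment; the wrist yaw tracks the
    arc tangent and the hand lifts during release.

    ``release_segment`` metadata (start, stop seconds) is attached to the
    returned spec for tests that check where the peak lands.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if release_speed <= 0:
        raise ValueError("release_speed must be > 0")
    if not 0.0 <= windup_fraction <= 1.0:
        raise ValueError("windup_fraction must lie in [0, 1]")
    if duration < 5.0:
        raise ValueError("the throw phases need at least a 5 s capture")
    peak_rate = release_speed / radius
    if peak_rate > GYRO_FULL_SCALE_RAD:
        raise ValueError(
            f"infeasible kinematics: release_speed {release_speed} m/s at "
            f"radius {radius} m needs {np.degrees(peak_rate):.0f} deg/s, "
            f"beyond the ±2000 deg/s gyro full scale")

    # angular-velocity bumps on the arc (times scale with the capture)
    u = duration / 6.0
    windup = _Bump(-windup_fraction * 2.0 * np.pi / (1.2 * u / 2.0),
                   0.8 * u, 1.2 * u)
    turn = _Bump(2.0 * 2.0 * np.pi / (1.4 * u), 2.3 * u, 1.4 * u)
    release = _Bump(peak_rate, 3.9 * u, 1.0 * u)
    bumps = ([turn, release] if windup_fraction == 0.0
             else [windup, turn, release])

    lift_height = 0.4  # m of hand elevation during release

    def theta(t: float) -> float:
        return sum(b.integral(t) for b in bumps)

    def theta_rate(t: float) -> float:
        return sum(b.value(t) for b in bumps)

    def theta_acc(t: float) -> float:
        return sum(b.slope(t) for b in bumps)

    def z_of(t: float) -> float:  # NED: negative z is up
        v = t - release.s
        if v <= 0.0 or v >= release.d:
            return -lift_height if v > 0.0 else 0.0
        return -lift_height * np.sin(0.5 * np.pi * v / release.d) ** 2

    def dz_of(t: float) -> float:
        v = t - release.s
        if v <= 0.0 or v >= release.d:
            return 0.0
        return -lift_height * 0.5 * np.pi / release.d \
            * np.sin(np.pi * v / release.d)

    def ddz_of(t: float) -> float:
        v = t - release.s
        if v <= 0.0 or v >= release.d:
            return 0.0
        return -lift_height * 0.5 * (np.pi / release.d) ** 2 \
            * np.cos(np.pi * v / release.d)

    def position(t: float) -> np.ndarray:
        th = theta(t)
        return np.array([radius * np.sin(th),
                         radius * (1.0 - np.cos(th)),
                         z_of(t)])

    def velocity(t: float) -> np.ndarray:
        th, thd = theta(t), theta_rate(t)
        return np.array([radius * thd * np.cos(th),
                         radius * thd * np.sin(th),
                         dz_of(t)])

    def acceleration(t: float) -> np.ndarray:
        th, thd, thdd = theta(t), theta_rate(t), theta_acc(t)
        return np.array([
            radius * (thdd * np.cos(th) - thd * thd * np.sin(th)),
            radius * (thdd * np.sin(th) + thd * thd * np.cos(th)),
            ddz_of(t)])

    def attitude(t: float) -> np.ndarray:
        # wrist yaw tracks the arc tangent
        return quat_from_axis_angle(_Z_AXIS, theta(t))

    def angular_rate(t: float) -> np.ndarray:
        return np.array([0.0, 0.0, theta_rate(t)])

    spec = TrajectorySpec(
        name="discus", duration=duration,
        position=position, velocity=velocity, acceleration=acceleration,
        attitude=attitude, angular_rate=angular_rate)
    spec.release_segment = (release.s, release.s + release.d)
    return spec


PRESETS = {
    "stationary": stationary_preset,
    "out_and_back": out_and_back_preset,
    "circle": circle_preset,
    "discus": discus_throw_preset,
}


def make_preset(name: str, **params) -> TrajectorySpec:
    """Build a preset trajectory by name (see :data:`PRESETS`)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: "
                         f"{sorted(PRESETS)}") from None
    return factory(**params)
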