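"""Dead-reckoning kinematics: from a 9-DoF capture to trajectory and speed.

The processing chain mirrors the firmware of a wrist-worn capture device:

1.  fuse the 9-DoF stream into a per-sample orientation (``wristkin.fusion``);
2.  rotate each body-frame accelerometer sample into the earth (NED) frame;
3.  subtract gravity → dynamic acceleration;
4.  smooth with a trailing N-sample moving mean (N = 50 by default);
5.  integrate (rectangle rule) to velocity;
6.  high-pass the velocity to strip the DC drift that integration accretes;
7.  zero-velocity update (ZUPT): any run of ≥ ``zupt_count`` consecutive
    samples whose dynamic acceleration stays inside ±``zupt_limit`` on all
    three axes has its velocity forced to exactly 0.0;
8.  speed = per-sample Euclidean norm of the velocity;
9.  integrate the corrected velocity to position, starting at (0, 0, 0).

The default capture regime is 3000 samples at a 0.002 s period (a 6 s
capture at 500 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import FusionConfig, OrientationTrack, fuse_capture
from .quaternion import quat_to_rotation_matrix

__all__ = [
    "DEFAULT_SAMPLE_PERIOD",
    "DEFAULT_N_SAMPLES",
    "STANDARD_GRAVITY",
    "ImuCapture",
    "PipelineConfig",
    "KinematicTrack",
    "remove_gravity",
    "smooth_acceleration",
    "integrate_rectangles",
    "remove_dc",
    "zero_velocity_update",
    "speed_magnitude",
    "process_capture",
    "read_capture_csv",
    "write_capture_csv",
    "read_track_csv",
    "write_track_csv",
]

DEFAULT_SAMPLE_PERIOD = 0.002   # s
DEFAULT_N_SAMPLES = 3000        # → a 6 s capture
STANDARD_GRAVITY = 9.80665      # m/s²


@dataclass
class ImuCapture:
    """A fixed-rate 9-DoF capture: the pipeline's input.

    ``accel_xyz`` (m/s², specific force), ``gyro_xyz`` (rad/s) and
    ``mag_xyz`` (gauss) are ``(n, 3)`` arrays on NED body axes.
    """

    sample_period: float
    accel_xyz: np.ndarray
    gyro_xyz: np.ndarray
    mag_xyz: np.ndarray

    def __post_init__(self) -> None:
        self.accel_xyz = np.atleast_2d(np.asarray(self.accel_xyz, float))
        self.gyro_xyz = np.atleast_2d(np.asarray(self.gyro_xyz, float))
        self.mag_xyz = np.atleast_2d(np.asarray(self.mag_xyz, float))
        if self.sample_period <= 0:
            raise ValueError("sample_period must be > 0")
        n = len(self.accel_xyz)
        for name, arr in (("accel_xyz", self.accel_xyz),
                          ("gyro_xyz", self.gyro_xyz),
                          ("mag_xyz", self.mag_xyz)):
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), "
                                 f"got {arr.shape}")

    @property
    def n_samples(self) -> int:
        return len(self.accel_xyz)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_period

    @property
    def duration(self) -> float:
        """Capture duration in seconds (n samples × sample period)."""
        return self.n_samples * self.sample_period

    def head(self, seconds: float) -> "ImuCapture":
        """The first ``seconds`` of the capture (e.g. the warm-up segment)."""
        k = int(round(seconds / self.sample_period))
        return ImuCapture(self.sample_period, self.accel_xyz[:k],
                          self.gyro_xyz[:k], self.mag_xyz[:k])


@dataclass
class PipelineConfig:
    """Tunables of the processing chain (device defaults).

    ``highpass_cutoff`` defaults to the device's printed 50 Hz.  Note that a
    genuine first-order 50 Hz high-pass passes only a few percent of the
    sub-10 Hz band where human limb motion lives; for trajectory
    reconstruction use :meth:`reconstruction`, which keeps every other
    default but sets a 0.1 Hz drift-removal cutoff.
    """

    smoothing_window: int = 50        # samples (N)
    highpass_cutoff: float = 50.0     # Hz
    zupt_limit: float = 0.3           # m/s²
    zupt_count: int = 60              # consecutive samples
    gravity_magnitude: float = STANDARD_GRAVITY
    smoothing_mode: str = "boxcar"    # "boxcar" | "exponential"

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.zupt_count < 1:
            raise ValueError("zupt_count must be >= 1")
        if self.zupt_limit <= 0:
            raise ValueError("zupt_limit must be > 0")
        if self.smoothing_mode not in ("boxcar", "exponential"):
            raise ValueError("smoothing_mode must be 'boxcar' or "
                             "'exponential'")

    @classmethod
    def reconstruction(cls, **overrides) -> "PipelineConfig":
        """Device defaults with a 0.1 Hz drift-removal high-pass."""
        overrides.setdefault("highpass_cutoff", 0.1)
        return cls(**overrides)


@dataclass
class KinematicTrack:
    """Per-sample earth-frame kinematics: the pipeline's output."""

    t: np.ndarray
    accel_earth: np.ndarray   # (n, 3) smoothed dynamic acceleration, m/s²
    velocity: np.ndarray      # (n, 3) m/s, after DC removal and ZUPT
    position: np.ndarray      # (n, 3) m, starts at (0, 0, 0)
    speed: np.ndarray         # (n,) m/s
    zupt_mask: np.ndarray     # (n,) bool, True where ZUPT zeroed velocity

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# individual processing steps
# ---------------------------------------------------------------------------

def remove_gravity(accel_earth, g: float = STANDARD_GRAVITY) -> np.ndarray:
    """Subtract the gravity reaction from earth-frame accelerometer samples.

    In NED, gravity is ``+g`` along Down, so a stationary sensor's
    earth-frame specific force is ``(0, 0, −g)``; adding ``(0, 0, +g)`` to
    the Down component leaves the dynamic acceleration.
    """
    a = np.atleast_2d(np.asarray(accel_earth, float)).copy()
    a[:, 2] += g
    return a


def smooth_acceleration(signal, N: int, mode: str = "boxcar") -> np.ndarray:
    """Causal trailing moving mean over N samples (per column).

    The device firmware labels this an EWMA, but the computation it describes
    — sum the last N samples and divide by N, recomputed at every new sample
    — is an equal-weight (boxcar) moving mean, which is what ``mode="boxcar"``
    implements.  ``mode="exponential"`` provides a true exponentially
    weighted mean with smoothing factor ``2/(N+1)`` for users who read the
    name strictly.  Startup samples use the mean of the samples seen so far.
    """
    x = np.asarray(signal, float)
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > x.shape[0]:
        raise ValueError(f"N={N} exceeds signal length {x.shape[0]}")
    if mode == "exponential":
        alpha = 2.0 / (N + 1.0)
        return pd.DataFrame(x).ewm(alpha=alpha, adjust=True).mean().to_numpy() \
            .reshape(x.shape)
    squeeze = x.ndim == 1
    x2 = x[:, None] if squeeze else x
    c = np.vstack([np.zeros((1, x2.shape[1])), np.cumsum(x2, axis=0)])
    idx = np.arange(1, x2.shape[0] + 1)
    lo = np.maximum(idx - N, 0)
    out = (c[idx] - c[lo]) / (idx - lo)[:, None]
    return out[:, 0] if squeeze else out


def integrate_rectangles(signal, dt: float, initial=0.0) -> np.ndarray:
    """Rectangle-rule running integral: cumulative sum of ``signal·dt``.

    Each sample contributes a rectangle of height ``signal[i]`` and width
    ``dt``; the output at sample ``i`` is ``initial`` plus the sum of the
    first ``i+1`` rectangles.  Used both for acceleration→velocity and for
    velocity→position (the latter deliberately unfiltered).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = np.asarray(signal, float)
    return np.asarray(initial, float) + np.cumsum(x, axis=0) * dt


def remove_dc(velocity, cutoff: float, fs: float) -> np.ndarray:
    """First-order single-pole high-pass: strips the DC/drift component.

    Discrete realization ``y[n] = α (y[n−1] + x[n] − x[n−1])`` with
    ``α = RC/(RC + 1/fs)`` and ``RC = 1/(2π·cutoff)``.  A constant input
    decays toward zero; components well above the cutoff pass unattenuated.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2}); "
                         f"got {cutoff}")
    from scipy.signal import lfilter
    rc = 1.0 / (2.0 * np.pi * cutoff)
    alpha = rc / (rc + 1.0 / fs)
    x = np.asarray(velocity, float)
    return lfilter([alpha, -alpha], [1.0, -alpha], x, axis=0)


def _quiet_runs(quiet: np.ndarray, count: int):
    """Start/stop (half-open) of maximal True-runs of length >= count."""
    q = np.concatenate([[False], quiet, [False]]).astype(int)
    d = np.diff(q)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(a, b) for a, b in zip(starts, stops) if b - a >= count]


def zero_velocity_update(dyn_accel, velocity, limit: float,
                         count: int) -> tuple[np.ndarray, np.ndarray]:
    """ZUPT: zero the velocity over sustained quiet acceleration windows.

    A sample is *quiet* when all three dynamic-acceleration components lie
    strictly inside ``(−limit, +limit)``.  Every maximal run of at least
    ``count`` consecutive quiet samples has all velocity components set to
    exactly 0.0 over the entire run; everything else is untouched.

    Returns ``(corrected_velocity, zeroed_mask)``.
    """
    if limit <= 0:
        raise ValueError("limit must be > 0")
    if count < 1:
        raise ValueError("count must be >= 1")
    a = np.atleast_2d(np.asarray(dyn_accel, float))
    v = np.atleast_2d(np.asarray(velocity, float)).copy()
    if a.shape != v.shape:
        raise ValueError("dyn_accel and velocity must be aligned")
    quiet = np.all(np.abs(a) < limit, axis=1)
    mask = np.zeros(len(v), dtype=bool)
    for start, stop in _quiet_runs(quiet, count):
        v[start:stop] = 0.0
        mask[start:stop] = True
    return v, mask


def speed_magnitude(vx, vy, vz) -> np.ndarray:
    """Instantaneous speed ``√(Vx² + Vy² + Vz²)`` per sample."""
    vx, vy, vz = (np.asarray(c, float) for c in (vx, vy, vz))
    if not vx.shape == vy.shape == vz.shape:
        raise ValueError("vx, vy, vz must have equal lengths")
    return np.sqrt(vx * vx + vy * vy + vz * vz)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}' failed: "
                                  f"{exc}") from exc
            return False
    return _StageContext()


class _StageError(RuntimeError):
    pass


def process_capture(capture: ImuCapture,
                    fusion_cfg: FusionConfig | None = None,
                    cfg: PipelineConfig | None = None,
                    orientation: OrientationTrack | None = None,
                    ) -> KinematicTrack:
    """Run the full chain on a capture and return the kinematic track.

    ``orientation`` may supply a precomputed orientation track (e.g. ground
    truth in tests); otherwise the fusion filter is run on the capture.
    Any stage failure is re-raised naming the stage.
    """
    fusion_cfg = fusion_cfg or FusionConfig(sample_period=capture.sample_period)
    cfg = cfg or PipelineConfig()
    dt = capture.sample_period
    fs = 1.0 / dt

    with _stage("fusion"):
        track = orientation if orientation is not None \
            else fuse_capture(capture, fusion_cfg)
        if len(track) != capture.n_samples:
            raise ValueError("orientation track length != capture length")

    with _stage("rotation to earth frame"):
        accel_earth = np.empty_like(capture.accel_xyz)
        for i, q in enumerate(track.quaternions):
            accel_earth[i] = quat_to_rotation_matrix(q).T @ capture.accel_xyz[i]

    with _stage("gravity removal"):
        dyn = remove_gravity(accel_earth, cfg.gravity_magnitude)

    with _stage("acceleration smoothing"):
        dyn_s = smooth_acceleration(dyn, cfg.smoothing_window,
                                    cfg.smoothing_mode)

    with _stage("velocity integration"):
        vel = integrate_rectangles(dyn_s, dt, np.zeros(3))

    with _stage("DC removal"):
        vel_hp = remove_dc(vel, cfg.highpass_cutoff, fs)

    with _stage("zero-velocity update"):
        vel_z, mask = zero_velocity_update(dyn_s, vel_hp, cfg.zupt_limit,
                                           cfg.zupt_count)

    with _stage("speed"):
        speed = speed_magnitude(vel_z[:, 0], vel_z[:, 1], vel_z[:, 2])

    with _stage("position integration"):
        # Integrate the corrected velocity; force the stated (0,0,0) origin.
        pos = integrate_rectangles(vel_z, dt, np.zeros(3))
        pos = np.vstack([np.zeros(3), pos[:-1]])

    return KinematicTrack(t=capture.t, accel_earth=dyn_s, velocity=vel_z,
                          position=pos, speed=speed, zupt_mask=mask)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CAPTURE_COLS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]
_TRACK_COLS = ["t", "ax_e", "ay_e", "az_e", "vx", "vy", "vz",
               "x", "y", "z", "speed"]


def write_capture_csv(capture: ImuCapture, path) -> None:
    """Capture → CSV with a commented units header."""
    df = pd.DataFrame(
        np.column_stack([capture.t, capture.accel_xyz, capture.gyro_xyz,
                         capture.mag_xyz]),
        columns=_CAPTURE_COLS)
    with open(path, "w") as fh:
        fh.write("# wristkin IMU capture; t [s], ax..az [m/s^2], "
                 "gx..gz [rad/s], mx..mz [gauss]; NED body axes\n")
        fh.write(f"# sample_period = {capture.sample_period!r} s\n")
        df.to_csv(fh, index=False)


def read_capture_csv(path) -> ImuCapture:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CAPTURE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"capture file {path} is missing columns {missing}")
    if len(df) < 2:
        raise ValueError(f"capture file {path} has fewer than 2 samples")
    t = df["t"].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    return ImuCapture(
        sample_period=dt,
        accel_xyz=df[["ax", "ay", "az"]].to_numpy(float),
        gyro_xyz=df[["gx", "gy", "gz"]].to_numpy(float),
        mag_xyz=df[["mx", "my", "mz"]].to_numpy(float),
    )


def write_track_csv(track: KinematicTrack, path) -> None:
    df = pd.DataFrame(
        np.column_stack([track.t, track.accel_earth, track.velocity,
                         track.position, track.speed]),
        columns=_TRACK_COLS)
    with open(path, "w") as fh:
        fh.write("# wristkin kinematic track; t [s], ax_e..az_e [m/s^2], "
                 "vx..vz [m/s], x..z [m], speed [m/s]; earth NED frame\n")
        df.to_csv(fh, index=False)


def read_track_csv(path) -> KinematicTrack:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _TRACK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} is missing columns {missing}")
    vel = df[["vx", "vy", "vz"]].to_numpy(float)
    return KinematicTrack(
        t=df["t"].to_numpy(float),
        accel_earth=df[["ax_e", "ay_e", "az_e"]].to_numpy(float),
        velocity=vel,
        position=df[["x", "y", "z"]].to_numpy(float),
        speed=df["speed"].to_numpy(float),
        zupt_mask=np.all(vel == 0.0, axis=1),
    )
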