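"""Per-axis offset/slope calibration and raw-count conversion.

The capture device digitizes each sensor at 16 bits over a configurable full
scale (±8 g accelerometer, ±2000 dps gyroscope, ±8 gauss magnetometer) and
applies a linear per-axis calibration ``calibrated = (raw − offset) · slope``
before any processing.  This module applies given calibration constants and
converts raw counts to physical units; it does not estimate constants from
maneuvers (see :func:`estimate_accel_offsets` for a convenience helper that
is *not* part of the device's documented procedure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "AxisCalibration",
    "CalibrationParams",
    "SensorScale",
    "ACCEL_SCALE",
    "GYRO_SCALE",
    "MAG_SCALE",
    "TABLE_LSB_SIZES",
    "apply_calibration",
    "counts_to_units",
    "estimate_accel_offsets",
    "load_calibration",
]


@dataclass
class AxisCalibration:
    offset: np.ndarray  # (3,), sensor units
    slope: np.ndarray   # (3,), dimensionless gain

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, float).reshape(3)
        self.slope = np.asarray(self.slope, float).reshape(3)
        if np.any(self.slope == 0.0):
            raise ValueError("calibration slopes must be nonzero")


def _identity_axis() -> AxisCalibration:
    return AxisCalibration(offset=np.zeros(3), slope=np.ones(3))


@dataclass
class CalibrationParams:
    """Offset/slope constants for the three sensors (identity by default)."""

    accelerometer: AxisCalibration = field(default_factory=_identity_axis)
    gyroscope: AxisCalibration = field(default_factory=_identity_axis)
    magnetometer: AxisCalibration = field(default_factory=_identity_axis)


@dataclass(frozen=True)
class SensorScale:
    """Full scale and digitizer depth of one sensor channel."""

    full_scale: float  # physical units (one-sided, e.g. 8 for ±8 g)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.full_scale <= 0:
            raise ValueError("full_scale must be > 0")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be > 0")

    @property
    def lsb(self) -> float:
        """Physical size of one count: 2·FS / 2^bits."""
        return 2.0 * self.full_scale / (1 << self.bit_depth)


ACCEL_SCALE = SensorScale(full_scale=8.0)      # ±8 g
GYRO_SCALE = SensorScale(full_scale=2000.0)    # ±2000 dps
MAG_SCALE = SensorScale(full_scale=8.0)        # ±8 gauss

#: LSB sizes as printed on the device's sensor datasheet.  Only the
#: accelerometer value (0.244 mg) equals 2·FS/2^16; the gyroscope
#: (70 mdps) and magnetometer (0.29 mgauss) figures are trimmed datasheet
#: sensitivities, kept here as data.
TABLE_LSB_SIZES = {
    "accelerometer": 0.244e-3,   # g/LSB
    "gyroscope": 70e-3,          # dps/LSB
    "magnetometer": 0.29e-3,     # gauss/LSB
}


def apply_calibration(raw, params: AxisCalibration) -> np.ndarray:
    """``(raw − offset) · slope`` per axis over a (n, 3) sequence."""
    r = np.atleast_2d(np.asarray(raw, float))
    if r.shape[1] != 3:
        raise ValueError("raw must be a sequence of 3-vectors")
    return (r - params.offset) * params.slope


def invert_calibration(calibrated, params: AxisCalibration) -> np.ndarray:
    """Analytic inverse of :func:`apply_calibration`."""
    c = np.atleast_2d(np.asarray(calibrated, float))
    return c / params.slope + params.offset


def counts_to_units(counts, scale: SensorScale):
    """Convert signed digitizer counts to physical units.

    ``value = counts · 2·FS/2^bits``; linear and odd.  Counts outside the
    signed range of ``bit_depth`` bits are rejected.
    """
    c = np.asarray(counts)
    lo = -(1 << (scale.bit_depth - 1))
    hi = (1 << (scale.bit_depth - 1)) - 1
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError(f"counts outside signed {scale.bit_depth}-bit range "
                         f"[{lo}, {hi}]")
    out = c * scale.lsb
    return float(out) if np.isscalar(counts) else out


def estimate_accel_offsets(stationary_accel, g: float = 9.80665,
                           down_axis: int = 2) -> np.ndarray:
    """Accelerometer offsets from a stationary, level segment (convenience).

    Assumes the device sat level with ``down_axis`` along NED Down, where the
    expected specific-force reading is ``−g``; the offset is the mean reading
    minus the expectation.  This helper is a package convenience, not the
    device's documented calibration procedure.
    """
    a = np.atleast_2d(np.asarray(stationary_accel, float))
    expected = np.zeros(3)
    expected[down_axis] = -g
    return a.mean(axis=0) - expected


def load_calibration(path) -> CalibrationParams:
    """Load constants from a YAML file.

    Layout: one key per sensor, each with ``offset`` and ``slope`` 3-lists::

        accelerometer: {offset: [0, 0, 0], slope: [1, 1, 1]}
        gyroscope:     {offset: [0, 0, 0], slope: [1, 1, 1]}
        magnetometer:  {offset: [0, 0, 0], slope: [1, 1, 1]}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for sensor in ("accelerometer", "gyroscope", "magnetometer"):
        if sensor in data:
            entry = data[sensor]
            kwargs[sensor] = AxisCalibration(
                offset=np.asarray(entry.get("offset", [0, 0, 0]), float),
                slope=np.asarray(entry.get("slope", [1, 1, 1]), float),
            )
    return CalibrationParams(**kwargs)
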