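"""Fixed-width 20-byte telemetry frame codec.

The capture device ships each processed sample to the display client over a
low-energy radio link whose payload is capped at 20 bytes per frame.  One
frame carries one sample's ``(x, y, z, speed)`` as four fixed-decimal ASCII
fields of exactly 5 bytes each in ``xx.xx`` format — e.g. position
``(1.2, 3.4, 5.6)`` at speed ``7.8`` encodes as ``b"01.2003.4005.6007.80"``.
A full default capture of 3000 samples therefore encodes to exactly
60 000 bytes.

The ``xx.xx`` field has no sign and spans 00.00–99.99, but reconstructed
coordinates can be negative.  Two explicit behaviors are provided:

* ``mode="offset"`` (default): each coordinate axis is shifted by a
  per-capture constant so the minimum lands at 0.00; the offsets are
  returned/stored as a header record (JSON sidecar for file streams) so the
  decoder can undo the shift.
* ``mode="strict"``: negative values are rejected.

Values are quantized to 2 decimals by round-half-away-from-zero before
encoding, so encode→decode is exact on quantized inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FRAME_SIZE",
    "FIELD_SIZE",
    "FIELD_MAX",
    "TelemetryError",
    "quantize",
    "encode_frame",
    "decode_frame",
    "encode_capture",
    "decode_stream",
    "write_stream",
    "read_stream",
]

FRAME_SIZE = 20
FIELD_SIZE = 5
FIELD_MAX = 99.99
_FIELDS = ("x", "y", "z", "speed")


class TelemetryError(ValueError):
    """Raised on unrepresentable values or malformed frames."""


def quantize(value: float) -> float:
    """Round to 2 decimals, half away from zero (platform-deterministic)."""
    v = np.asarray(value, float)
    return float(np.sign(v) * np.floor(np.abs(v) * 100.0 + 0.5) / 100.0) + 0.0


def _encode_field(value: float, name: str) -> bytes:
    q = quantize(value)
    if q < 0.0:
        raise TelemetryError(f"field '{name}' is negative ({q}); use offset "
                             "mode to shift coordinates into range")
    if q > FIELD_MAX:
        raise TelemetryError(f"field '{name}' overflows the xx.xx format: "
                             f"{q} > {FIELD_MAX}")
    return f"{q:05.2f}".encode("ascii")


def encode_frame(x: float, y: float, z: float, speed: float) -> bytes:
    """One 20-byte payload: four 5-byte ``xx.xx`` fields, order x,y,z,speed."""
    payload = b"".join(_encode_field(v, n)
                       for v, n in zip((x, y, z, speed), _FIELDS))
    assert len(payload) == FRAME_SIZE
    return payload


def decode_frame(payload: bytes) -> tuple[float, float, float, float]:
    """Recover ``(x, y, z, speed)`` from one 20-byte payload."""
    if len(payload) != FRAME_SIZE:
        raise TelemetryError(f"frame must be exactly {FRAME_SIZE} bytes, "
                             f"got {len(payload)}")
    values = []
    for k in range(4):
        off = k * FIELD_SIZE
        raw = payload[off:off + FIELD_SIZE]
        try:
            text = raw.decode("ascii")
            if text[2] != "." or not (text[:2] + text[3:]).isdigit():
                raise ValueError
            values.append(float(text))
        except (ValueError, UnicodeDecodeError):
            raise TelemetryError(
                f"unparseable field '{_FIELDS[k]}' at byte offset {off}: "
                f"{raw!r}") from None
    return tuple(values)


@dataclass(frozen=True)
class StreamHeader:
    """Per-capture axis offsets (the documented side channel of offset mode).

    ``decoded_value = field_value + offset`` per axis; speed is never offset.
    """

    x_offset: float = 0.0
    y_offset: float = 0.0
    z_offset: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x_offset, self.y_offset, self.z_offset, 0.0])


def encode_capture(track, mode: str = "offset"
                   ) -> tuple[list[bytes], StreamHeader]:
    """Encode a kinematic track, one frame per sample, in sample order.

    ``track`` is a :class:`wristkin.kinematics.KinematicTrack` (or any object
    with ``position`` (n, 3) and ``speed`` (n,)).  Returns the frame list and
    the header record of axis offsets (all zero in strict mode).
    """
    if mode not in ("offset", "strict"):
        raise ValueError("mode must be 'offset' or 'strict'")
    pos = np.atleast_2d(np.asarray(track.position, float))
    speed = np.asarray(track.speed, float)
    if pos.shape[0] == 0:
        return [], StreamHeader()
    if mode == "offset":
        mins = np.minimum(pos.min(axis=0), 0.0)
        # floor to the 0.01 grid so every shifted value is >= 0
        offsets = np.floor(mins * 100.0) / 100.0
        header = StreamHeader(*offsets)
    else:
        header = StreamHeader()
    shift = header.as_array()[:3]
    frames = []
    for i in range(pos.shape[0]):
        try:
            frames.append(encode_frame(pos[i, 0] - shift[0],
                                       pos[i, 1] - shift[1],
                                       pos[i, 2] - shift[2],
                                       speed[i]))
        except TelemetryError as exc:
            raise TelemetryError(f"sample {i}: {exc}") from None
    return frames, header


def decode_stream(data: bytes, header: StreamHeader | None = None
                  ) -> np.ndarray:
    """Concatenated frames → (n, 4) array of (x, y, z, speed).

    Rejects streams whose length is not a multiple of 20 bytes, naming the
    offending (truncated) frame.
    """
    if len(data) % FRAME_SIZE != 0:
        raise TelemetryError(
            f"stream length {len(data)} is not a multiple of {FRAME_SIZE}: "
            f"frame {len(data) // FRAME_SIZE} is truncated")
    n = len(data) // FRAME_SIZE
    out = np.empty((n, 4))
    for i in range(n):
        try:
            out[i] = decode_frame(data[i * FRAME_SIZE:(i + 1) * FRAME_SIZE])
        except TelemetryError as exc:
            raise TelemetryError(f"frame {i}: {exc}") from None
    if header is not None:
        out += header.as_array()
    return out


def write_stream(frames: list[bytes], header: StreamHeader, path) -> None:
    """Write a binary stream of concatenated frames + a JSON offset sidecar."""
    with open(path, "wb") as fh:
        fh.write(b"".join(frames))
    with open(str(path) + ".offsets.json", "w") as fh:
        json.dump({"x_offset": header.x_offset, "y_offset": header.y_offset,
                   "z_offset": header.z_offset}, fh)


def read_stream(path) -> np.ndarray:
    """Read a stream file (applying its offset sidecar when present)."""
    with open(path, "rb") as fh:
        data = fh.read()
    header = StreamHeader()
    sidecar = str(path) + ".offsets.json"
    try:
        with open(sidecar) as fh:
            header = StreamHeader(**json.load(fh))
    except FileNotFoundError:
        pass
    return decode_stream(data, header)
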