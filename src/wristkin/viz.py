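"""The four standard plots of a processed capture.

Mirrors what the display client draws from the telemetry stream: the 3D
trajectory, its top (XY) and side (XZ) views, and instantaneous speed versus
sample number.  The movement origin (0, 0, 0) is marked on every spatial
plot.  Rendering is deterministic for a fixed track and options.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; must precede pyplot import

import matplotlib.pyplot as plt  # noqa: E402

from .kinematics import KinematicTrack  # noqa: E402

__all__ = ["plot_track", "plot_stabilization"]


def _require_nonempty(track: KinematicTrack) -> None:
    if len(track) == 0:
        raise ValueError("cannot plot an empty track")


def plot_track(track: KinematicTrack, out_dir, prefix: str = "track",
               dpi: int = 110) -> list[Path]:
    """Write the four plot files; returns their paths in a fixed order."""
    _require_nonempty(track)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x, y, z = track.position.T
    paths = []

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot(x, y, z, lw=1.2)
    ax.scatter([0], [0], [0], color="red", s=30, label="origin (0,0,0)")
    ax.set_xlabel("x north [m]")
    ax.set_ylabel("y east [m]")
    ax.set_zlabel("z down [m]")
    ax.invert_zaxis()  # NED: down positive, draw up as up
    ax.set_title("3D trajectory")
    ax.legend(loc="upper left")
    p = out_dir / f"{prefix}_3d.png"
    fig.savefig(p, dpi=dpi)
    plt.close(fig)
    paths.append(p)

    for (u, v, ul, vl, name, title) in (
            (x, y, "x north [m]", "y east [m]", "top_xy", "Top view (XY)"),
            (x, z, "x north [m]", "z down [m]", "side_xz", "Side view (XZ)")):
        fig, ax = plt.subplots(figsize=(5.5, 5))
        ax.plot(u, v, lw=1.2)
        ax.plot([0], [0], "ro", ms=6, label="origin")
        ax.set_xlabel(ul)
        ax.set_ylabel(vl)
        if name == "side_xz":
            ax.invert_yaxis()
        ax.set_title(title)
        ax.set_aspect("equal", adjustable="datalim")
        ax.legend()
        p = out_dir / f"{prefix}_{name}.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        paths.append(p)

    fig, ax = plt.subplots(figsize=(6.5, 4))
    ax.plot(range(len(track)), track.speed, lw=1.0)
    ax.set_xlabel("sample number")
    ax.set_ylabel("speed [m/s]")
    ax.set_title("Instantaneous speed")
    p = out_dir / f"{prefix}_speed.png"
    fig.savefig(p, dpi=dpi)
    plt.close(fig)
    paths.append(p)
    return paths


def plot_stabilization(euler_history, out_path, dpi: int = 110) -> Path:
    """Warm-up yaw/pitch/roll vs sample (the stabilization plot)."""
    fig, ax = plt.subplots(figsize=(6.5, 4))
    for i, label in enumerate(("yaw", "pitch", "roll")):
        ax.plot(euler_history[:, i], lw=1.0, label=label)
    ax.set_xlabel("sample number")
    ax.set_ylabel("angle [deg]")
    ax.set_title("Fusion stabilization")
    ax.legend()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path
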