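"""Graphic outputs: pressure maps, statokinesiograms, stabilograms.

Pressure maps use a blue (low) to red (high) colour scale fixed by default
to [sensitivity floor, calibration cap] so sensor saturation cannot wash
out the contrast between pressure ranges.  Markers (limb COPs, maximal-
pressure points, body COP) are drawn as distinct circles in platform mm
coordinates.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import patches

from .core import PressureRecording, ValidationError
from .sway import CopTrajectory, EllipseFit

__all__ = ["render_pressure_map", "render_statokinesiogram",
           "render_stabilogram"]

_MARKER_STYLE = {
    "limb_cop_left": dict(mfc="black", mec="white", label="limb COP (L)"),
    "limb_cop_right": dict(mfc="black", mec="white", label="limb COP (R)"),
    "max_pressure_left": dict(mfc="white", mec="black", label="max pressure (L)"),
    "max_pressure_right": dict(mfc="white", mec="black", label="max pressure (R)"),
    "body_cop": dict(mfc="0.5", mec="black", label="body COP"),
}


def _extent_mm(rec: PressureRecording) -> tuple[float, float, float, float]:
    spec = rec.spec
    half = spec.sensor_pitch_mm / 2.0
    x0, y0 = spec.cell_center_mm(0, 0)
    x1, y1 = spec.cell_center_mm(spec.grid_rows - 1, spec.grid_cols - 1)
    return (float(x0 - half), float(x1 + half), float(y1 - half), float(y0 + half))


def render_pressure_map(rec: PressureRecording, frame_index: int,
                        path, markers: dict | None = None,
                        mode: str = "2d",
                        vmax_kPa: float | None = None) -> Path:
    """Render one frame as a 2-D or 3-D colour pressure map.

    ``markers`` maps marker names (keys of the legend: ``limb_cop_left``,
    ``max_pressure_left``, ``body_cop``, ...) to (x, y) platform mm.
    """
    if not 0 <= frame_index < rec.n_frames:
        raise ValidationError(
            f"frame_index {frame_index} outside 0..{rec.n_frames - 1}")
    if mode not in ("2d", "3d"):
        raise ValidationError("mode must be '2d' or '3d'")
    spec = rec.spec
    vmin = spec.pressure_floor_kPa
    vmax = vmax_kPa if vmax_kPa is not None else spec.calibration_cap_kPa
    frame = rec.frames[frame_index]
    cmap = plt.get_cmap("jet").copy()
    cmap.set_under("white")

    if mode == "2d":
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(frame, extent=_extent_mm(rec), origin="upper",
                       cmap=cmap, vmin=vmin, vmax=vmax)
        fig.colorbar(im, ax=ax, label="pressure (kPa)")
        for name, (x, y) in (markers or {}).items():
            style = _MARKER_STYLE.get(name, dict(mfc="none", mec="black",
                                                 label=name))
            ax.plot([x], [y], marker="o", ms=10, ls="none", **style)
        if markers:
            ax.legend(loc="upper right", fontsize=7)
        ax.set_xlabel("x (latero-lateral, mm)")
        ax.set_ylabel("y (craniocaudal, mm)")
    else:
        fig = plt.figure(figsize=(7, 6))
        ax = fig.add_subplot(projection="3d")
        X, Y = spec.sensor_centers_mm()
        surf = ax.plot_surface(X, Y, frame, cmap=cmap, vmin=vmin, vmax=vmax,
                               rcount=spec.grid_rows, ccount=spec.grid_cols)
        fig.colorbar(surf, ax=ax, shrink=0.6, label="pressure (kPa)")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_zlabel("kPa")
    ax.set_title(f"{rec.subject_id} / {rec.trial_id} frame {frame_index}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_statokinesiogram(traj: CopTrajectory, ellipse: EllipseFit,
                            path) -> Path:
    """COP migration in the X-Y plane with its 90% coverage ellipse."""
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(traj.x_mm, traj.y_mm, "-", lw=0.6, color="tab:green", alpha=0.8)
    ax.plot(traj.x_mm, traj.y_mm, ".", ms=2, color="tab:green")
    cx, cy = ellipse.center_xy_mm
    if not ellipse.degenerate:
        e = patches.Ellipse((cx, cy),
                            width=2 * ellipse.semi_axis_major_mm,
                            height=2 * ellipse.semi_axis_minor_mm,
                            angle=math.degrees(ellipse.orientation_rad),
                            fill=False, color="black", lw=1.5)
        ax.add_patch(e)
        ax.set_title(f"statokinesiogram: {ellipse.area_mm2:.2f} mm$^2$ "
                     f"({ellipse.coverage:.0%})")
    else:
        ax.set_title("statokinesiogram: degenerate (zero-area) ellipse")
    ax.plot([cx], [cy], "k+", ms=8)
    ax.set_xlabel("x (latero-lateral, mm)")
    ax.set_ylabel("y (craniocaudal, mm)")
    ax.set_aspect("equal")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_stabilogram(traj: CopTrajectory, path) -> Path:
    """X(t) and Y(t) COP oscillation traces on separate panels."""
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    ax1.plot(traj.t_s, traj.x_mm, color="tab:green", lw=0.8)
    ax1.set_ylabel("x (mm)")
    ax1.set_title("stabilogram")
    ax2.plot(traj.t_s, traj.y_mm, color="tab:green", lw=0.8)
    ax2.set_ylabel("y (mm)")
    ax2.set_xlabel("time (s)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
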