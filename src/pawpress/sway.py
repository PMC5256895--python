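"""Body-COP trajectory, statokinesiogram ellipse, stabilogram summaries.

The statokinesiogram quantifies postural sway as the area of the ellipse
containing 90% of the body-COP samples.  Following posturographic
convention this is the 90% *prediction* ellipse under a bivariate-normal
model: with sample covariance Σ (n-1 denominator) and eigenvalues
λ₁ ≥ λ₂, the semi-axes are sqrt(χ²_{0.90,2}·λᵢ) along the eigenvectors and

    area = π · χ²_{0.90,2} · sqrt(λ₁ λ₂),   χ²_{0.90,2} ≈ 4.60517.

An empirical alternative — the covariance-shaped ellipse scaled to cover
exactly ⌈0.9 n⌉ points — is available for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DegenerateEllipseError, PressureRecording, ValidationError
from .segmentation import PawSegmentation

__all__ = ["CopTrajectory", "EllipseFit", "StabilogramSummary",
           "body_cop_trajectory", "fit_prediction_ellipse",
           "empirical_coverage", "stabilogram_summary"]


@dataclass
class CopTrajectory:
    """Body-COP time series in platform mm (all active sensors pooled)."""

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        n = len(self.t_s)
        if len(self.x_mm) != n or len(self.y_mm) != n:
            raise ValidationError("t, x, y must have equal length")
        if n and not (np.isfinite(self.x_mm).all()
                      and np.isfinite(self.y_mm).all()):
            raise ValidationError("non-finite COP coordinates")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])


@dataclass
class EllipseFit:
    """A coverage ellipse of the COP point cloud.

    ``area_mm2 == pi * semi_major * semi_minor``; ``degenerate`` flags fits
    from too few or collinear points (zero area, axes 0).
    """

    center_xy_mm: tuple[float, float]
    semi_axis_major_mm: float
    semi_axis_minor_mm: float
    orientation_rad: float
    area_mm2: float
    coverage: float = 0.90
    degenerate: bool = False


@dataclass
class StabilogramSummary:
    """Per-axis location/dispersion of the COP time series."""

    mean_x_mm: float
    mean_y_mm: float
    sd_x_mm: float
    sd_y_mm: float
    range_x_mm: float
    range_y_mm: float


def body_cop_trajectory(rec: PressureRecording,
                        seg: PawSegmentation | None = None) -> CopTrajectory:
    """Per-frame pressure-weighted centroid over ALL active sensors.

    The body COP is limb-agnostic: both limbs and any unassigned midline
    sensors contribute.  Frames with no active sensor are dropped with a
    warning.
    """
    X, Y = rec.spec.sensor_centers_mm()
    p = np.where(rec.frames >= rec.spec.pressure_floor_kPa, rec.frames, 0.0)
    tot = p.sum(axis=(1, 2))
    keep = tot > 0
    if not keep.any():
        raise ValidationError("every frame is empty; no COP trajectory")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty frame(s) from "
                      "the COP trajectory", stacklevel=2)
    t = np.arange(rec.n_frames) / rec.spec.sampling_hz
    cx = (p * X).sum(axis=(1, 2))[keep] / tot[keep]
    cy = (p * Y).sum(axis=(1, 2))[keep] / tot[keep]
    return CopTrajectory(t[keep], cx, cy)


def _as_xy(traj) -> np.ndarray:
    if isinstance(traj, CopTrajectory):
        return traj.xy
    return np.asarray(traj, dtype=float).reshape(-1, 2)


def fit_prediction_ellipse(traj, coverage: float = 0.90,
                           method: str = "normal") -> EllipseFit:
    """Fit the coverage ellipse of a COP point cloud.

    ``method='normal'`` (default) is the χ²-quantile prediction ellipse;
    ``method='empirical'`` rescales the covariance-shaped ellipse so it
    covers exactly ⌈coverage·n⌉ of the points.  Fewer than 3 points or a
    rank-deficient covariance yield a degenerate (zero-area) fit.
    """
    if not 0 < coverage < 1:
        raise ValidationError("coverage must be in (0, 1)")
    xy = _as_xy(traj)
    n = len(xy)
    center = tuple(xy.mean(axis=0)) if n else (0.0, 0.0)
    if n < 3:
        return EllipseFit(center, 0.0, 0.0, 0.0, 0.0, coverage, degenerate=True)
    cov = np.cov(xy, rowvar=False, ddof=1)
    lam, vec = np.linalg.eigh(cov)          # ascending eigenvalues
    if lam[0] <= max(1e-12 * max(lam[1], 1.0), 0.0):
        return EllipseFit(center, 0.0, 0.0, 0.0, 0.0, coverage, degenerate=True)
    if method == "normal":
        k = stats.chi2.ppf(coverage, df=2)
    elif method == "empirical":
        centered = xy - np.asarray(center)
        d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(cov), centered)
        m = math.ceil(coverage * n)
        k = float(np.sort(d2)[m - 1])
    else:
        raise ValidationError(f"unknown ellipse method {method!r}")
    major = math.sqrt(k * lam[1])
    minor = math.sqrt(k * lam[0])
    angle = math.atan2(vec[1, 1], vec[0, 1])  # principal eigenvector
    if angle < 0:
        angle += math.pi                      # orientation is mod pi
    return EllipseFit(center, major, minor, angle,
                      math.pi * major * minor, coverage)


def empirical_coverage(traj, ellipse: EllipseFit) -> float:
    """Fraction of points inside the ellipse (ellipse coordinate <= 1)."""
    if ellipse.degenerate or ellipse.semi_axis_minor_mm <= 0:
        raise DegenerateEllipseError("coverage undefined for a degenerate fit")
    xy = _as_xy(traj) - np.asarray(ellipse.center_xy_mm)
    c, s = math.cos(ellipse.orientation_rad), math.sin(ellipse.orientation_rad)
    u = xy[:, 0] * c + xy[:, 1] * s
    v = -xy[:, 0] * s + xy[:, 1] * c
    q = (u / ellipse.semi_axis_major_mm) ** 2 + (v / ellipse.semi_axis_minor_mm) ** 2
    return float((q <= 1.0).mean())


def stabilogram_summary(traj: CopTrajectory) -> StabilogramSummary:
    """Mean, SD (n-1) and peak-to-peak range of each COP axis."""
    xy = _as_xy(traj)
    if len(xy) == 0:
        raise ValidationError("empty trajectory")
    sd = xy.std(axis=0, ddof=1) if len(xy) > 1 else np.zeros(2)
    rng = xy.max(axis=0) - xy.min(axis=0)
    return StabilogramSummary(
        mean_x_mm=float(xy[:, 0].mean()), mean_y_mm=float(xy[:, 1].mean()),
        sd_x_mm=float(sd[0]), sd_y_mm=float(sd[1]),
        range_x_mm=float(rng[0]), range_y_mm=float(rng[1]),
    )
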