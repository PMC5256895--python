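"""Per-limb static parameters and limb-asymmetry indices.

The six static posturographic parameters of a standing trial, per limb:
percentage load share, contact area (cm²), mean and maximum pressure (kPa),
limb centre of pressure (COP), and the maximal-pressure point.  Asymmetry
indices compare the two limbs: the load-share difference in percentage
points, and relative differences (normalised by the two-limb mean) for
area, mean pressure and — formula selectable — maximum pressure.

All per-limb statistics use only frames that segmented cleanly into two
limbs; within a frame only active sensors (pressure at or above the device
floor) contribute.  Trial values are unweighted means over frames; maximum
pressure is peak-hold over the whole trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PressureRecording, SegmentationError
from .segmentation import PawSegmentation

__all__ = ["LimbParameters", "AsymmetryIndices", "limb_load_share",
           "paw_area", "limb_pressures", "limb_cop", "max_pressure_point",
           "compute_limb_parameters", "asymmetry_indices", "average_trials"]


@dataclass
class LimbParameters:
    """Trial-level static parameters for one limb."""

    limb: str
    load_share_pct: float
    area_cm2: float
    mean_pressure_kPa: float
    max_pressure_kPa: float
    limb_cop_xy_mm: tuple[float, float]
    max_pressure_point_xy_mm: tuple[float, float]

    _FIELDS = ("load_share_pct", "area_cm2", "mean_pressure_kPa",
               "max_pressure_kPa")


@dataclass
class AsymmetryIndices:
    """Between-limb asymmetry of one trial (or one subject).

    Relative differences are |a - b| / ((a + b) / 2) x 100; the load-share
    difference is in percentage points.  ``sl_limb`` names the limb with
    the higher load share (the sound limb in a unilaterally lame animal).
    """

    distribution_diff_pct: float
    area_diff_pct: float
    mean_pressure_diff_pct: float
    max_pressure_diff: float
    sl_limb: str
    max_pressure_formula: str = "mean_normalized"


def _clean_frames(rec: PressureRecording, seg: PawSegmentation) -> np.ndarray:
    idx = seg.clean_frames
    if idx.size == 0:
        raise SegmentationError("no frame segmented into two limbs")
    return idx


def limb_load_share(rec: PressureRecording,
                    seg: PawSegmentation) -> tuple[float, float]:
    """(left %, right %) of the two-limb pressure total, averaged over frames.

    Per frame the share is the limb's pressure sum over the left+right sum
    (unassigned sensors excluded); frames with a zero two-limb total are
    skipped.  The two returned shares sum to exactly 100.
    """
    idx = _clean_frames(rec, seg)
    frames = rec.frames[idx]
    lsum = np.where(seg.left_masks[idx], frames, 0.0).sum(axis=(1, 2))
    rsum = np.where(seg.right_masks[idx], frames, 0.0).sum(axis=(1, 2))
    tot = lsum + rsum
    keep = tot > 0
    if not keep.any():
        raise SegmentationError("all segmented frames carry zero pressure")
    share_l = float((lsum[keep] / tot[keep]).mean() * 100.0)
    return share_l, 100.0 - share_l


def paw_area(rec: PressureRecording, seg: PawSegmentation,
             limb: str) -> float:
    """Mean contact area of one limb in cm² (active-sensor count x sensor area)."""
    idx = _clean_frames(rec, seg)
    counts = seg.limb_masks(limb)[idx].sum(axis=(1, 2))
    if counts.sum() == 0:
        raise SegmentationError(f"{limb} limb mask empty in every frame")
    return float(counts.mean() * rec.spec.sensor_area_cm2)


def limb_pressures(rec: PressureRecording, seg: PawSegmentation,
                   limb: str) -> tuple[float, float]:
    """(mean kPa, max kPa) for one limb.

    Mean: per-frame mean over the limb's active sensors, averaged over
    frames with a non-empty mask.  Max: peak-hold — the single highest
    sensor reading in the limb mask over the whole trial.
    """
    idx = _clean_frames(rec, seg)
    frames = rec.frames[idx]
    masks = seg.limb_masks(limb)[idx]
    counts = masks.sum(axis=(1, 2))
    keep = counts > 0
    if not keep.any():
        raise SegmentationError(f"{limb} limb mask empty in every frame")
    sums = np.where(masks, frames, 0.0).sum(axis=(1, 2))
    mean_p = float((sums[keep] / counts[keep]).mean())
    max_p = float(np.where(masks, frames, 0.0).max())
    return mean_p, max_p


def limb_cop(rec: PressureRecording, seg: PawSegmentation,
             limb: str) -> tuple[float, float]:
    """Pressure-weighted centroid of one limb in platform mm, frame-averaged."""
    idx = _clean_frames(rec, seg)
    X, Y = rec.spec.sensor_centers_mm()
    masks = seg.limb_masks(limb)[idx]
    p = np.where(masks, rec.frames[idx], 0.0)
    tot = p.sum(axis=(1, 2))
    keep = tot > 0
    if not keep.any():
        raise SegmentationError(f"{limb} limb carries no pressure")
    cx = (p * X).sum(axis=(1, 2))[keep] / tot[keep]
    cy = (p * Y).sum(axis=(1, 2))[keep] / tot[keep]
    return float(cx.mean()), float(cy.mean())


def max_pressure_point(rec: PressureRecording, seg: PawSegmentation,
                       limb: str) -> tuple[float, float]:
    """Platform-mm location of the limb's single highest sensor reading.

    Ties are broken by first occurrence in (frame, row, col) order.
    """
    idx = _clean_frames(rec, seg)
    p = np.where(seg.limb_masks(limb)[idx], rec.frames[idx], 0.0)
    if p.max() <= 0:
        raise SegmentationError(f"{limb} limb carries no pressure")
    t, r, c = np.unravel_index(int(np.argmax(p)), p.shape)
    x, y = rec.spec.cell_center_mm(r, c)
    return float(x), float(y)


def compute_limb_parameters(rec: PressureRecording, seg: PawSegmentation,
                            ) -> dict[str, LimbParameters]:
    """All six static parameters for both limbs of one trial."""
    share_l, share_r = limb_load_share(rec, seg)
    out = {}
    for limb, share in (("left", share_l), ("right", share_r)):
        mean_p, max_p = limb_pressures(rec, seg, limb)
        out[limb] = LimbParameters(
            limb=limb,
            load_share_pct=share,
            area_cm2=paw_area(rec, seg, limb),
            mean_pressure_kPa=mean_p,
            max_pressure_kPa=max_p,
            limb_cop_xy_mm=limb_cop(rec, seg, limb),
            max_pressure_point_xy_mm=max_pressure_point(rec, seg, limb),
        )
    return out


def _rel_diff_pct(a: float, b: float) -> float:
    m = 0.5 * (a + b)
    return 0.0 if m == 0 else abs(a - b) / m * 100.0


def asymmetry_indices(left: LimbParameters, right: LimbParameters,
                      max_pressure_formula: str = "mean_normalized",
                      ) -> AsymmetryIndices:
    """Between-limb asymmetry indices.

    The load-distribution difference is the absolute difference of the two
    shares (percentage points; equals SL share - LL share since shares sum
    to 100).  Area and mean-pressure differences are normalised by the
    two-limb mean.  The maximum-pressure difference formula is selectable:
    ``mean_normalized`` (default), ``ll_normalized`` (relative to the lower
    value) or ``absolute`` (kPa).
    """
    sl = "left" if left.load_share_pct >= right.load_share_pct else "right"
    a, b = left.max_pressure_kPa, right.max_pressure_kPa
    if max_pressure_formula == "mean_normalized":
        maxdiff = _rel_diff_pct(a, b)
    elif max_pressure_formula == "ll_normalized":
        lo = min(a, b)
        maxdiff = 0.0 if lo == 0 else abs(a - b) / lo * 100.0
    elif max_pressure_formula == "absolute":
        maxdiff = abs(a - b)
    else:
        raise ValueError(f"unknown max-pressure formula {max_pressure_formula!r}")
    return AsymmetryIndices(
        distribution_diff_pct=abs(left.load_share_pct - right.load_share_pct),
        area_diff_pct=_rel_diff_pct(left.area_cm2, right.area_cm2),
        mean_pressure_diff_pct=_rel_diff_pct(left.mean_pressure_kPa,
                                             right.mean_pressure_kPa),
        max_pressure_diff=maxdiff,
        sl_limb=sl,
        max_pressure_formula=max_pressure_formula,
    )


def average_trials(trials: list) -> object:
    """Unweighted per-field mean across valid trials.

    Accepts a list of :class:`LimbParameters` (same limb) or
    :class:`AsymmetryIndices`; subject-level values are conventionally the
    average of three successive standing trials.
    """
    if not trials:
        raise ValueError("need at least one valid trial")
    first = trials[0]
    if isinstance(first, LimbParameters):
        if any(t.limb != first.limb for t in trials):
            raise ValueError("cannot average parameters of different limbs")
        mean = lambda f: float(np.mean([getattr(t, f) for t in trials]))
        mean_xy = lambda f: tuple(np.mean([getattr(t, f) for t in trials],
                                          axis=0))
        return LimbParameters(
            limb=first.limb,
            load_share_pct=mean("load_share_pct"),
            area_cm2=mean("area_cm2"),
            mean_pressure_kPa=mean("mean_pressure_kPa"),
            max_pressure_kPa=mean("max_pressure_kPa"),
            limb_cop_xy_mm=mean_xy("limb_cop_xy_mm"),
            max_pressure_point_xy_mm=mean_xy("max_pressure_point_xy_mm"),
        )
    if isinstance(first, AsymmetryIndices):
        mean = lambda f: float(np.mean([getattr(t, f) for t in trials]))
        sides = [t.sl_limb for t in trials]
        return AsymmetryIndices(
            distribution_diff_pct=mean("distribution_diff_pct"),
            area_diff_pct=mean("area_diff_pct"),
            mean_pressure_diff_pct=mean("mean_pressure_diff_pct"),
            max_pressure_diff=mean("max_pressure_diff"),
            sl_limb=max(set(sides), key=sides.count),
            max_pressure_formula=first.max_pressure_formula,
        )
    raise TypeError(f"cannot average {type(first).__name__}")
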