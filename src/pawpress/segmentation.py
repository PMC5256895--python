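"""Partition active sensors into left and right paw prints; trial validity.

A standing forelimb trial shows two prints side by side, each fragmenting
into up to five connected components (the pads may not touch at 1 cm
resolution).  Components are clustered into limbs by splitting at the
largest latero-lateral gap between component centroids, provided that gap
exceeds a minimum separation — a single print must not be split in two.
Frames that do not resolve into exactly two clusters are flagged and their
sensors left unassigned.

Trial validity implements the immobility rule: a valid recording requires
the animal to stand completely still, checked as bounded footprint-centroid
drift, bounded contact-area variation, and two clusters in every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .core import PressureRecording, SegmentationError

__all__ = ["PawSegmentation", "StillnessReport", "activation_mask",
           "label_paws", "check_stillness"]

#: minimum latero-lateral centroid gap (mm) accepted as an inter-limb split
MIN_SPLIT_GAP_MM = 30.0


def activation_mask(frame: np.ndarray, floor: float) -> np.ndarray:
    """Boolean grid: True exactly where pressure >= floor (inclusive)."""
    return np.asarray(frame) >= floor


@dataclass
class PawSegmentation:
    """Per-frame left/right paw masks for a recording.

    ``n_clusters`` is the number of limb clusters resolved per frame (2 for
    a clean two-print frame); sensors of frames with ``n_clusters != 2``
    are all unassigned.  ``stable_left``/``stable_right`` are the
    union-over-time footprints of cleanly segmented frames.
    """

    left_masks: np.ndarray    # (T, R, C) bool
    right_masks: np.ndarray
    unassigned_masks: np.ndarray
    n_components: np.ndarray  # connected components per frame
    n_clusters: np.ndarray    # limb clusters per frame
    stable_left: np.ndarray = field(init=False)
    stable_right: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.stable_left = self.left_masks.any(axis=0)
        self.stable_right = self.right_masks.any(axis=0)

    @property
    def clean_frames(self) -> np.ndarray:
        """Indices of frames that resolved into exactly two limbs."""
        return np.flatnonzero(self.n_clusters == 2)

    def limb_masks(self, limb: str) -> np.ndarray:
        if limb not in ("left", "right"):
            raise ValueError("limb must be 'left' or 'right'")
        return self.left_masks if limb == "left" else self.right_masks


def label_paws(rec: PressureRecording,
               min_split_gap_mm: float = MIN_SPLIT_GAP_MM) -> PawSegmentation:
    """Segment every frame into left/right paw prints.

    Connected components (8-connectivity) of the activation mask are
    clustered by splitting the x-sorted component centroids at their
    largest gap when that gap is at least ``min_split_gap_mm``; the
    left/right labels follow centroid x (the animal faces +y).
    """
    spec = rec.spec
    floor = spec.pressure_floor_kPa
    T = rec.n_frames
    shape = (T, spec.grid_rows, spec.grid_cols)
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    unassigned = np.zeros(shape, dtype=bool)
    n_comp = np.zeros(T, dtype=int)
    n_clust = np.zeros(T, dtype=int)

    any_active = False
    for t in range(T):
        active = activation_mask(rec.frames[t], floor)
        if not active.any():
            continue
        any_active = True
        labels, n = measure.label(active, connectivity=2, return_num=True)
        n_comp[t] = n
        if n == 1:
            n_clust[t] = 1
            unassigned[t] = active
            continue
        # centroid x (mm) per component, pressure-agnostic (cell count)
        cx = np.empty(n)
        for k in range(1, n + 1):
            rr, cc = np.nonzero(labels == k)
            x, _ = spec.cell_center_mm(rr, cc)
            cx[k - 1] = x.mean()
        order = np.argsort(cx)
        gaps = np.diff(cx[order])
        split = int(np.argmax(gaps))
        if gaps[split] < min_split_gap_mm:
            n_clust[t] = 1
            unassigned[t] = active
            continue
        # any further gap comparable to the split gap means >2 clusters
        other = np.delete(gaps, split)
        if other.size and other.max() >= min_split_gap_mm:
            n_clust[t] = 3
            unassigned[t] = active
            continue
        n_clust[t] = 2
        left_ids = {int(order[i]) + 1 for i in range(split + 1)}
        lmask = np.isin(labels, list(left_ids)) & active
        left[t] = lmask
        right[t] = active & ~lmask

    if not any_active:
        raise SegmentationError("no active sensors in any frame")
    return PawSegmentation(left, right, unassigned, n_comp, n_clust)


@dataclass
class StillnessReport:
    """Outcome of the immobility validity screen for one trial."""

    valid: bool
    max_drift_mm: dict          # limb -> max centroid excursion from mean
    area_cv: dict               # limb -> coefficient of variation of area
    n_bad_frames: int           # frames without exactly 2 clusters
    failed_criteria: list

    def to_dict(self) -> dict:
        return {"valid": bool(self.valid),
                "max_drift_mm": {k: float(v) for k, v in self.max_drift_mm.items()},
                "area_cv": {k: float(v) for k, v in self.area_cv.items()},
                "n_bad_frames": int(self.n_bad_frames),
                "failed_criteria": list(self.failed_criteria)}


def check_stillness(rec: PressureRecording, seg: PawSegmentation,
                    max_drift_mm: float = 10.0,
                    max_area_cv: float = 0.15) -> StillnessReport:
    """Screen a trial against the immobility rule.

    Valid iff every frame has exactly two limb clusters, each limb's
    footprint centroid stays within ``max_drift_mm`` of its trial mean, and
    each limb's contact area has coefficient of variation at most
    ``max_area_cv``.
    """
    spec = rec.spec
    failed = []
    n_bad = int((seg.n_clusters != 2).sum())
    if n_bad > 0:
        failed.append("clusters")

    drift = {}
    area_cv = {}
    clean = seg.clean_frames
    for limb in ("left", "right"):
        masks = seg.limb_masks(limb)[clean] if clean.size else np.zeros((0,))
        if clean.size == 0:
            drift[limb] = float("nan")
            area_cv[limb] = float("nan")
            continue
        cents = np.empty((len(clean), 2))
        areas = np.empty(len(clean))
        for i, m in enumerate(masks):
            rr, cc = np.nonzero(m)
            x, y = spec.cell_center_mm(rr, cc)
            cents[i] = (x.mean(), y.mean())
            areas[i] = len(rr)
        excursion = np.linalg.norm(cents - cents.mean(axis=0), axis=1)
        drift[limb] = float(excursion.max())
        mean_area = areas.mean()
        area_cv[limb] = float(areas.std() / mean_area) if mean_area > 0 else 0.0
        if drift[limb] > max_drift_mm and "drift" not in failed:
            failed.append("drift")
        if area_cv[limb] > max_area_cv and "area_cv" not in failed:
            failed.append("area_cv")

    return StillnessReport(valid=not failed, max_drift_mm=drift,
                           area_cv=area_cv, n_bad_frames=n_bad,
                           failed_criteria=failed)
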