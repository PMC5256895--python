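"""End-to-end per-trial analysis and cohort-table assembly.

One function runs the full chain for a recording — segmentation, validity
screen, per-limb parameters, asymmetry indices, body-COP sway — and flat
helpers turn lists of analysed trials into the tables the group statistics
consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PressureRecording
from .posturometrics import (AsymmetryIndices, LimbParameters,
                             asymmetry_indices, compute_limb_parameters)
from .segmentation import (PawSegmentation, StillnessReport, check_stillness,
                           label_paws)
from .sway import (CopTrajectory, EllipseFit, StabilogramSummary,
                   body_cop_trajectory, fit_prediction_ellipse,
                   stabilogram_summary)

__all__ = ["TrialAnalysis", "analyze_recording", "trials_to_table",
           "subject_table", "cohort_long_table"]


@dataclass
class TrialAnalysis:
    """Everything the pipeline derives from one standing trial."""

    recording: PressureRecording
    segmentation: PawSegmentation
    stillness: StillnessReport
    limbs: dict[str, LimbParameters]
    asymmetry: AsymmetryIndices
    trajectory: CopTrajectory
    ellipse: EllipseFit
    stabilogram: StabilogramSummary

    @property
    def valid(self) -> bool:
        return self.stillness.valid


def analyze_recording(rec: PressureRecording,
                      max_drift_mm: float = 10.0,
                      max_area_cv: float = 0.15,
                      ellipse_coverage: float = 0.90,
                      max_pressure_formula: str = "mean_normalized",
                      ) -> TrialAnalysis:
    """Segment a recording and compute all static parameters and sway."""
    seg = label_paws(rec)
    stillness = check_stillness(rec, seg, max_drift_mm, max_area_cv)
    limbs = compute_limb_parameters(rec, seg)
    asym = asymmetry_indices(limbs["left"], limbs["right"],
                             max_pressure_formula)
    traj = body_cop_trajectory(rec, seg)
    ellipse = fit_prediction_ellipse(traj, coverage=ellipse_coverage)
    return TrialAnalysis(rec, seg, stillness, limbs, asym, traj, ellipse,
                         stabilogram_summary(traj))


def trials_to_table(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    """Flat per-(trial, limb) parameter table plus sway columns."""
    rows = []
    for a in analyses:
        rec = a.recording
        for limb, lp in a.limbs.items():
            rows.append({
                "subject": rec.subject_id, "trial": rec.trial_id,
                "limb": limb, "valid": a.valid,
                "load_share_pct": lp.load_share_pct,
                "area_cm2": lp.area_cm2,
                "mean_kpa": lp.mean_pressure_kPa,
                "max_kpa": lp.max_pressure_kPa,
                "cop_x_mm": lp.limb_cop_xy_mm[0],
                "cop_y_mm": lp.limb_cop_xy_mm[1],
                "maxp_x_mm": lp.max_pressure_point_xy_mm[0],
                "maxp_y_mm": lp.max_pressure_point_xy_mm[1],
                "sway_area_mm2": a.ellipse.area_mm2,
                "sway_sd_x_mm": a.stabilogram.sd_x_mm,
                "sway_sd_y_mm": a.stabilogram.sd_y_mm,
                "asym_distribution_pct": a.asymmetry.distribution_diff_pct,
                "asym_area_pct": a.asymmetry.area_diff_pct,
                "asym_mean_pressure_pct": a.asymmetry.mean_pressure_diff_pct,
                "asym_max_pressure": a.asymmetry.max_pressure_diff,
                "sl_limb": a.asymmetry.sl_limb,
            })
    return pd.DataFrame(rows)


def subject_table(trial_table: pd.DataFrame,
                  require_valid: bool = True) -> pd.DataFrame:
    """Average each subject's valid trials (per limb) into one row each."""
    df = trial_table
    if require_valid and "valid" in df.columns:
        kept = df[df["valid"]]
        if not kept.empty:
            df = kept
    num = df.select_dtypes(include=[np.number]).columns
    out = df.groupby(["subject", "limb"], as_index=False)[list(num)].mean()
    n_trials = df.groupby(["subject", "limb"]).size().rename("n_trials")
    return out.merge(n_trials.reset_index(), on=["subject", "limb"])


def cohort_long_table(subjects: pd.DataFrame,
                      manifest: pd.DataFrame) -> pd.DataFrame:
    """Build the long cohort table for :mod:`pawpress.stats`.

    ``subjects`` is the per-(subject, limb) table from
    :func:`subject_table`; ``manifest`` maps subject -> (group, day) and may
    carry a ``dog`` column naming the physical animal when the same dog was
    measured under several conditions (the long table's subject is then the
    dog, so day contrasts pair correctly).  Limb roles are assigned per
    subject by load share: SL carries the higher share, LL the lower (for
    sound controls these are simply the higher/lesser-value limbs).
    """
    missing = set(subjects["subject"]) - set(manifest["subject"])
    if missing:
        raise ValueError(f"subjects absent from manifest: {sorted(missing)}")
    cols = ["subject", "group", "day"] + (
        ["dog"] if "dog" in manifest.columns else [])
    merged = subjects.merge(manifest[cols].drop_duplicates(), on="subject")
    if "dog" not in merged.columns:
        merged["dog"] = merged["subject"]
    rows = []
    limb_params = [("load_share_pct", "pressure_distribution"),
                   ("area_cm2", "paw_area"),
                   ("mean_kpa", "mean_pressure"),
                   ("max_kpa", "max_pressure")]
    asym_params = [("asym_distribution_pct", "pressure_distribution_diff"),
                   ("asym_area_pct", "paw_area_diff"),
                   ("asym_mean_pressure_pct", "mean_pressure_diff"),
                   ("asym_max_pressure", "max_pressure_diff")]
    for subject, sdf in merged.groupby("subject"):
        group = sdf["group"].iloc[0]
        day = sdf["day"].iloc[0]
        dog = sdf["dog"].iloc[0]
        by_share = sdf.sort_values("load_share_pct")
        roles = dict(zip(by_share["limb"], ["LL", "SL"]))
        for _, r in sdf.iterrows():
            role = roles[r["limb"]]
            for col, pname in limb_params:
                rows.append({"subject": dog, "group": group, "day": day,
                             "parameter": pname, "limb_role": role,
                             "value": r[col]})
        first = sdf.iloc[0]
        for col, pname in asym_params:
            rows.append({"subject": dog, "group": group, "day": day,
                         "parameter": pname, "limb_role": "NA",
                         "value": first[col]})
        rows.append({"subject": dog, "group": group, "day": day,
                     "parameter": "statokinesiogram_mm2", "limb_role": "NA",
                     "value": first["sway_area_mm2"]})
    return pd.DataFrame(rows)
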