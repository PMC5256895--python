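"""Render the study's graphic outputs for one sound and one lame dog.

For the first control trial and the first lame day-0 trial: the 2-D and
3-D colour pressure maps with limb COP / maximal-pressure / body-COP
markers, the statokinesiogram with its 90% ellipse, and the stabilogram.
"""

import sys

from common import RESULTS, study_cohort

from pawpress import analyze_recording
from pawpress.plotting import (render_pressure_map, render_stabilogram,
                               render_statokinesiogram)

FIGDIR = RESULTS / "figures"


def render_trial(rec, tag: str) -> None:
    a = analyze_recording(rec)
    lp = a.limbs
    markers = {"limb_cop_left": lp["left"].limb_cop_xy_mm,
               "limb_cop_right": lp["right"].limb_cop_xy_mm,
               "max_pressure_left": lp["left"].max_pressure_point_xy_mm,
               "max_pressure_right": lp["right"].max_pressure_point_xy_mm,
               "body_cop": (a.stabilogram.mean_x_mm, a.stabilogram.mean_y_mm)}
    render_pressure_map(rec, 0, FIGDIR / f"{tag}_pressure_2d.png",
                        markers=markers)
    render_pressure_map(rec, 0, FIGDIR / f"{tag}_pressure_3d.png", mode="3d")
    render_statokinesiogram(a.trajectory, a.ellipse,
                            FIGDIR / f"{tag}_statokinesiogram.png")
    render_stabilogram(a.trajectory, FIGDIR / f"{tag}_stabilogram.png")
    print(f"{tag}: shares ({lp['left'].load_share_pct:.2f}, "
          f"{lp['right'].load_share_pct:.2f}) %, "
          f"sway ellipse {a.ellipse.area_mm2:.2f} mm^2")


def main() -> int:
    recs, truth = study_cohort()
    by_subject = {}
    for r in recs:  # keep each subject's first trial
        by_subject.setdefault(r.subject_id, r)
    control = truth[truth.condition == "control"].subject.iloc[0]
    lame = truth[truth.condition == "lame_d0"].subject.iloc[0]
    FIGDIR.mkdir(parents=True, exist_ok=True)
    render_trial(by_subject[control], "sound")
    render_trial(by_subject[lame], "lame_d0")
    print(f"figures in {FIGDIR}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
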