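"""Simulate the study cohort and record its ground truth.

Generates 45 standing trials (5 dogs x 3 groups/conditions x 3 trials of
10 s at 100 Hz), writes the per-dog ground-truth table and the subject
manifest under results/, and drops one example recording bundle under
scratch/ for inspection.
"""

import sys

from common import RESULTS, SCRATCH, study_cohort

from pawpress import write_recording


def main() -> int:
    recs, truth = study_cohort()
    RESULTS.mkdir(exist_ok=True)
    truth.to_csv(RESULTS / "cohort_truth.csv", index=False)
    truth[["subject", "dog", "group", "day"]].to_csv(
        RESULTS / "subjects_manifest.csv", index=False)

    example = recs[0]
    bundle = write_recording(example, SCRATCH / "example_bundle"
                             / f"{example.subject_id}_{example.trial_id}")

    print(f"simulated {len(recs)} trials for {len(truth)} subject-sessions")
    print(truth.groupby("condition")[["true_asym_pct", "true_area_mm2"]]
          .mean().round(2))
    print(f"example bundle: {bundle}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
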