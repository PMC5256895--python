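"""Aggregate subject-level parameters into the cohort summary table.

Builds the long cohort table (limb roles assigned by load share: SL =
higher share, LL = lower), then the mean +/- SD and 95% CI per (group,
day, parameter, limb role) — the study's summary-table layout.
"""

import sys

import pandas as pd
from common import RESULTS

from pawpress import cohort_long_table, summarize_cohort


def main() -> int:
    subjects = pd.read_csv(RESULTS / "subject_parameters.csv")
    manifest = pd.read_csv(RESULTS / "subjects_manifest.csv")
    table = cohort_long_table(subjects, manifest)
    table.to_csv(RESULTS / "cohort_long.csv", index=False)

    summary = summarize_cohort(table)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)

    view = summary[summary.parameter.isin(
        ["pressure_distribution", "pressure_distribution_diff",
         "statokinesiogram_mm2"])]
    print(view.round(2).to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
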