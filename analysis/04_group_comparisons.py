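"""The study's significance tests on the synthetic cohort.

Per parameter: the limb contrast within the lame group at day 0, the
paired day-0 vs day-90 treatment contrast, and the day-90 vs control
between-group contrast with Tukey-adjusted pairwise p-values, each with
Shapiro (normality of residuals) and Levene (homoscedasticity) checks.
"""

import json
import sys

import pandas as pd
from common import RESULTS

from pawpress import compare


def main() -> int:
    table = pd.read_csv(RESULTS / "cohort_long.csv")
    results = []
    runs = [("limb-within-subject", "pressure_distribution",
             dict(group="lame", day=0)),
            ("limb-within-subject", "mean_pressure",
             dict(group="lame", day=0))]
    for param in ("pressure_distribution_diff", "paw_area_diff",
                  "mean_pressure_diff", "statokinesiogram_mm2"):
        runs.append(("day-within-subject", param, {}))
        runs.append(("group-between", param, dict(day=90)))

    for design, param, kw in runs:
        r = compare(table, design, param, **kw)
        results.append(r.to_dict())
        flags = []
        if not r.normal:
            flags.append("residuals non-normal")
        if not r.homoscedastic:
            flags.append("heteroscedastic")
        note = f"  [{', '.join(flags)}]" if flags else ""
        print(f"{param:30s} {r.contrast:28s} F={r.f_statistic:7.2f} "
              f"p={r.p_value:.4g}{note}")

    (RESULTS / "group_stats.json").write_text(json.dumps(results, indent=2))
    print(f"\nwrote {len(results)} contrasts to results/group_stats.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
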