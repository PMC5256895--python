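"""Cohort aggregation and significance testing.

Works on a long cohort table with one row per (subject, day, parameter,
limb role): columns ``subject, group, day, parameter, limb_role, value``
with ``group`` in {'control', 'lame'}, ``day`` in {0, 90} for the lame
group (-1 / missing for controls) and ``limb_role`` in {'LL', 'SL', 'NA'}
(lame/lesser-value vs sound/higher-value limb; 'NA' for limb-agnostic
parameters such as the sway-ellipse area).

Three comparison designs mirror the study's contrasts:

* ``limb-within-subject`` — LL vs SL paired within subjects of one cell;
* ``day-within-subject`` — day 0 vs day 90 paired within lame subjects;
* ``group-between`` — lame (at one day) vs control, one-way ANOVA with
  Tukey-adjusted pairwise contrasts.

Each result carries a Shapiro-Wilk test of residual normality and a Levene
test of homoscedasticity, flagged at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["ComparisonResult", "summarize_cohort", "compare",
           "COHORT_COLUMNS"]

COHORT_COLUMNS = ("subject", "group", "day", "parameter", "limb_role", "value")

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One tested contrast with its assumption checks."""

    contrast: str
    parameter: str
    f_statistic: float
    p_value: float
    tukey: list = field(default_factory=list)   # dicts: pair, meandiff, p_adj
    shapiro_p: float = float("nan")
    levene_p: float = float("nan")
    alpha: float = ALPHA

    @property
    def normal(self) -> bool:
        return not (self.shapiro_p < self.alpha)

    @property
    def homoscedastic(self) -> bool:
        return not (self.levene_p < self.alpha)

    def to_dict(self) -> dict:
        return {"contrast": self.contrast, "parameter": self.parameter,
                "F": self.f_statistic, "p": self.p_value,
                "tukey": self.tukey, "shapiro_p": self.shapiro_p,
                "levene_p": self.levene_p, "alpha": self.alpha,
                "normal": self.normal, "homoscedastic": self.homoscedastic}


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    return table


def summarize_cohort(table: pd.DataFrame,
                     ci_level: float = 0.95) -> pd.DataFrame:
    """Mean ± SD and t-based CI per (group, day, parameter, limb role).

    The CI convention is mean ± t_{(1+level)/2, n-1} · SD/√n; cells with a
    single subject get a degenerate CI at the mean, empty cells are
    omitted.  SD uses the n-1 denominator.
    """
    _check_table(table)
    rows = []
    for (group, day, param, role), cell in table.groupby(
            ["group", "day", "parameter", "limb_role"], dropna=False):
        v = cell["value"].to_numpy(dtype=float)
        n = len(v)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = sps.t.ppf(0.5 + ci_level / 2, n - 1) * sd / np.sqrt(n)
        else:
            half = 0.0
        rows.append({"group": group, "day": day, "parameter": param,
                     "limb_role": role, "n": n, "mean": mean, "sd": sd,
                     "ci_low": mean - half, "ci_high": mean + half})
    return pd.DataFrame(rows)


def _shapiro_levene(groups: list[np.ndarray]) -> tuple[float, float]:
    residuals = np.concatenate([g - g.mean() for g in groups])
    if len(residuals) >= 3 and residuals.std() > 0:
        shapiro_p = float(sps.shapiro(residuals).pvalue)
    else:
        shapiro_p = float("nan")
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        try:
            levene_p = float(sps.levene(*groups).pvalue)
        except ValueError:
            levene_p = float("nan")
    else:
        levene_p = float("nan")
    return shapiro_p, levene_p


def _paired_rm_anova(wide: pd.DataFrame, within: str) -> tuple[float, float]:
    long = wide.reset_index().melt(id_vars="subject", var_name=within,
                                   value_name="value")
    res = AnovaRM(long, depvar="value", subject="subject",
                  within=[within]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def compare(table: pd.DataFrame, design: str, parameter: str,
            group: str = "lame", day: int | None = 0) -> ComparisonResult:
    """Run one of the study's contrasts on a cohort table.

    design='limb-within-subject': LL vs SL for ``parameter`` within the
    subjects of (group, day).  design='day-within-subject': day 0 vs 90
    within the lame group (limb-agnostic parameters or pre-computed
    differences).  design='group-between': lame at ``day`` vs control.
    """
    _check_table(table)
    sub = table[table["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")

    if design == "limb-within-subject":
        cell = sub[(sub["group"] == group)
                   & ((sub["day"] == day) | (group == "control"))]
        wide = cell.pivot(index="subject", columns="limb_role",
                          values="value").dropna()
        if wide.shape[0] < 2 or not {"LL", "SL"} <= set(wide.columns):
            raise ValueError(f"limb contrast needs >=2 subjects with both "
                             f"limb roles in {group}/day {day}")
        f, p = _paired_rm_anova(wide[["LL", "SL"]], "limb_role")
        groups = [wide["LL"].to_numpy(), wide["SL"].to_numpy()]
        label = f"{group} day {day}: LL vs SL"
    elif design == "day-within-subject":
        cell = sub[sub["group"] == "lame"]
        wide = cell.pivot_table(index="subject", columns="day",
                                values="value").dropna()
        if wide.shape[0] < 2 or wide.shape[1] < 2:
            raise ValueError("day contrast needs >=2 lame subjects seen on "
                             "both days")
        wide.columns = [f"d{int(c)}" for c in wide.columns]
        f, p = _paired_rm_anova(wide, "day")
        groups = [wide[c].to_numpy() for c in wide.columns]
        label = "lame: day 0 vs day 90"
    elif design == "group-between":
        lame = sub[(sub["group"] == "lame") & (sub["day"] == day)]
        ctrl = sub[sub["group"] == "control"]
        g1 = lame.groupby("subject")["value"].mean().to_numpy()
        g0 = ctrl.groupby("subject")["value"].mean().to_numpy()
        if len(g1) < 2 or len(g0) < 2:
            raise ValueError("group contrast needs >=2 subjects per group; "
                             f"got lame={len(g1)}, control={len(g0)}")
        f, p = sps.f_oneway(g1, g0)
        f, p = float(f), float(p)
        groups = [g1, g0]
        label = f"lame day {day} vs control"
    else:
        raise ValueError(f"unknown design {design!r}")

    tukey = []
    if design == "group-between":
        values = np.concatenate(groups)
        labels = np.array([f"lame_d{day}"] * len(groups[0])
                          + ["control"] * len(groups[1]))
        res = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
        from itertools import combinations
        pairs = list(combinations(res.groupsunique, 2))
        for (a, b), md, padj, rej in zip(pairs, res.meandiffs,
                                         res.pvalues, res.reject):
            tukey.append({"pair": f"{a} vs {b}", "meandiff": float(md),
                          "p_adj": float(padj), "reject": bool(rej)})
    else:
        # two paired levels: the RM-ANOVA F test IS the pairwise contrast
        tukey.append({"pair": label, "meandiff":
                      float(groups[1].mean() - groups[0].mean()),
                      "p_adj": p, "reject": bool(p < ALPHA)})

    shapiro_p, levene_p = _shapiro_levene(groups)
    return ComparisonResult(contrast=label, parameter=parameter,
                            f_statistic=f, p_value=p, tukey=tukey,
                            shapiro_p=shapiro_p, levene_p=levene_p)
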