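"""Shared study configuration for the numbered analysis scripts.

The cohort mirrors the study design: 5 sound control dogs and 5 dogs with
unilateral forelimb lameness, the latter recorded before treatment (day 0)
and at day 90, three 10-second standing trials per animal per session on a
48 x 48 cm, 100 Hz pressure platform.
"""

from pathlib import Path

from pawpress import simulate_cohort

COHORT_SEED = 20170123
N_PER_GROUP = 5
N_TRIALS = 3
DURATION_S = 10.0

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def study_cohort():
    """The seeded synthetic cohort every analysis step operates on."""
    return simulate_cohort(n_per_group=N_PER_GROUP, n_trials=N_TRIALS,
                           duration_s=DURATION_S, seed=COHORT_SEED)
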