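"""Shared fixtures: small seeded synthetic recordings.

Everything is generated at test time by the simulator; session scope keeps
the heavier standing trials from being rebuilt per test.
"""

import numpy as np
import pytest

from pawpress import PlatformSpec, SimulationConfig, simulate_recording
from pawpress.simulate import SwayModel

ZERO_SWAY = SwayModel.from_stationary_sd(0.0, 0.0)


def quiet_config(**kw) -> SimulationConfig:
    """Config with no sway, no jitter, no noise, no quantisation."""
    base = dict(sway=ZERO_SWAY, limb_jitter=ZERO_SWAY,
                noise_kPa=0.0, quantize_kPa=0.0)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def symmetric_quiet():
    """Deterministic 50/50 trial: zero sway, zero noise, 0.3 s."""
    rec, truth = simulate_recording(quiet_config(seed=1), duration_s=0.3,
                                    return_truth=True)
    return rec, truth


@pytest.fixture(scope="session")
def lame_trial():
    """Realistic 60/40 lame trial with default sway and noise, 2 s."""
    cfg = SimulationConfig(load_split=(0.3972, 0.6028), seed=11)
    rec, truth = simulate_recording(cfg, duration_s=2.0, return_truth=True)
    return rec, truth


@pytest.fixture(scope="session")
def default_spec():
    return PlatformSpec()
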