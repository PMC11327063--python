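"""Shared fixtures: simulated records reused across the test modules.

All fixtures are session-scoped because the wavelet transform is the
expensive step; tests must not mutate them.
"""
from __future__ import annotations

import numpy as np
import pytest

from scedr import cwt_morse, scedr as run_scedr
from scedr.simulate import Interferer, SimScenario, simulate_heart_rate


@pytest.fixture(scope="session")
def tone_record():
    """600 s record with constant 15 bpm breathing (0.25 Hz RSA tone)."""
    scenario = SimScenario(duration_s=600.0, hr_baseline=70.0, rsa_amplitude=2.0,
                           br_trajectory=15.0, seed=11)
    hr, truth = simulate_heart_rate(scenario)
    tfmap = cwt_morse(hr)
    return scenario, hr, truth, tfmap


@pytest.fixture(scope="session")
def ramp_record():
    """1200 s record with breathing ramping 12 -> 20 bpm."""
    scenario = SimScenario(duration_s=1200.0, br_trajectory=[(0.0, 12.0), (1200.0, 20.0)],
                           seed=12)
    hr, truth = simulate_heart_rate(scenario)
    tfmap = cwt_morse(hr)
    return scenario, hr, truth, tfmap


@pytest.fixture(scope="session")
def interferer_record():
    """Constant 15 bpm breathing with a 30 s, 2x-amplitude 0.35 Hz transient."""
    scenario = SimScenario(
        duration_s=600.0, rsa_amplitude=2.0, br_trajectory=15.0,
        interferers=[Interferer(300.0, 330.0, 0.35, 4.0)], seed=13,
    )
    hr, truth = simulate_heart_rate(scenario)
    tfmap = cwt_morse(hr)
    return scenario, hr, truth, tfmap


def epoch_means(values: np.ndarray, times: np.ndarray, epoch_len: float = 30.0):
    """Per-epoch means of a series, as (epoch_index, mean) arrays."""
    n = int(np.floor((times[-1] + 1e-9) / epoch_len))
    idx, means = [], []
    for k in range(n):
        sel = (times >= k * epoch_len) & (times < (k + 1) * epoch_len)
        if sel.any():
            idx.append(k)
            means.append(float(values[sel].mean()))
    return np.array(idx), np.array(means)
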