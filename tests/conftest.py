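"""Shared fixtures and helpers for the meanet test suite.

All synthetic inputs are generated programmatically and seeded; the
"reduced study" helpers build a desk-scale analogue of a chronic-exposure
plate (fewer electrodes, shorter recordings, lower event rates) used by
the end-to-end tests.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from meanet import CompoundEffect, SimConfig, SpikeTrain, simulate_experiment
from meanet.pipeline import RunConfig


def make_train(times, window=(0.0, 600.0), electrode=0) -> SpikeTrain:
    return SpikeTrain(electrode=electrode, spike_times=np.asarray(times, dtype=float), window=window)


def poisson_train(rng, rate_hz, duration_s, electrode=0) -> SpikeTrain:
    n = rng.poisson(rate_hz * duration_s)
    t = np.unique(rng.uniform(0.0, duration_s, n))
    return make_train(t, (0.0, duration_s), electrode)


def log_poisson_tail(n: int, mu: float) -> float:
    """Independent oracle: log P(X >= n) by direct term-by-term summation."""
    if n <= 0:
        return 0.0
    if mu == 0.0:
        return -math.inf
    terms = []
    k = n
    best = -math.inf
    while True:
        lt = k * math.log(mu) - mu - math.lgamma(k + 1)
        terms.append(lt)
        best = max(best, lt)
        if k > mu and lt < best - 80.0:
            break
        k += 1
    return best + math.log(sum(math.exp(t - best) for t in terms))


def reduced_sim_config(seed: int, **overrides) -> SimConfig:
    """Desk-scale study conditions: 6 electrodes, 10-min recordings,
    3 network bursts/min at plateau."""
    kw = dict(
        electrodes_per_well=6,
        recording_duration_s=600.0,
        baseline_network_burst_rate=3.0,
        within_burst_rate=60.0,
        burst_duration_mean_s=0.25,
        recruitment_fraction=0.8,
        background_rate=0.3,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def reduced_run_config(**overrides) -> RunConfig:
    kw = dict(recording_duration_s=600.0, n_electrodes=6, analysis_window_s=600.0)
    kw.update(overrides)
    return RunConfig(**kw)


def two_condition_design(n_per_cell: int, compound: str, conc: float) -> pd.DataFrame:
    """n wells per (condition x sex) cell: solvent controls plus one condition."""
    rows = []
    i = 0
    for comp, c in [("DMSO", 0.0)] * n_per_cell + [(compound, conc)] * n_per_cell:
        for sex in ("male", "female"):
            rows.append(dict(plate=0, well_index=i, compound=comp, concentration_um=c, sex=sex))
            i += 1
    return pd.DataFrame(rows)


def simulate_reduced_study(seed: int, effect: CompoundEffect | None, n_per_cell: int = 12,
                           **cfg_overrides):
    """Simulate the reduced chronic-exposure study; returns (recordings, design)."""
    cfg_overrides.setdefault("wells_per_plate", max(48, 4 * n_per_cell))
    cfg = reduced_sim_config(seed, **cfg_overrides)
    if effect is None:
        effect = CompoundEffect("SHAM", 10.0, {})  # i.i.d. copy of control
    design = two_condition_design(n_per_cell, effect.compound, effect.concentration_um)
    recs, plate_map = simulate_experiment(cfg, design, [effect])
    return recs, plate_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
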