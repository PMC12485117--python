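"""Shared fixtures: small synthetic experiments generated once per session.

Problem sizes are deliberately desk-scale (8×8×4 grids, tens of
sessions) so the whole suite runs in minutes; the generators still use
the study's trial structure (5 s stimuli, 30 s intervals, each session
one trial per odor, no immediate repeats).
"""

from __future__ import annotations

import numpy as np
import pytest

from odoresp import preprocess as pre
from odoresp import synthgen as sg


@pytest.fixture(scope="session")
def small_config() -> sg.SynthConfig:
    return sg.SynthConfig(
        grid_shape=(8, 8, 4),
        n_sessions=20,
        rest_duration=30.0,
        noise_sd=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_exp(small_config) -> sg.Experiment:
    return sg.generate_experiment(small_config)


@pytest.fixture(scope="session")
def small_dff(small_exp) -> dict[str, pre.DffTensor]:
    return {ch: pre.dff_from_experiment(small_exp, ch) for ch in small_exp.fluorescence}


@pytest.fixture(scope="session")
def small_trials(small_exp, small_dff) -> dict[str, pre.TrialTensor]:
    return {
        ch: pre.extract_trials(dff, small_exp.trial_table, 0, 14)
        for ch, dff in small_dff.items()
    }


@pytest.fixture(scope="session")
def noiseless_exp() -> sg.Experiment:
    """Single-channel, zero-noise experiment for parameter-recovery tests."""
    cfg = sg.SynthConfig(
        grid_shape=(8, 8, 4),
        n_sessions=6,
        rest_duration=30.0,
        noise_sd=0.0,
        channel_params={"calcium": sg.ChannelParams()},
        drift_schedule={"calcium": np.ones(6)},
        seed=3,
    )
    return sg.generate_experiment(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test draws from its own fixed stream, so
    # results never depend on which other tests ran first
    return np.random.default_rng(12345)
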