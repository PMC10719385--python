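"""Shared fixtures: a scaled-down synthetic experiment (10 trials/session)
and its preprocessed envelopes, generated once per test session."""

from __future__ import annotations

import numpy as np
import pytest

from mmgdecode import GeneratorConfig, generate_experiment, preprocess_recording
from mmgdecode.synthetic import default_session_plan


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_trials_per_session=10, session_plan=default_session_plan(10), seed=7
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config, seed=7)


@pytest.fixture(scope="session")
def small_envs(small_experiment):
    """(env_sets, events) for the scaled-down experiment."""
    env_sets = {"EMG": [], "MMG": []}
    events = []
    for rec_emg, rec_mmg, ev in small_experiment:
        env_sets["EMG"].append(preprocess_recording(rec_emg))
        env_sets["MMG"].append(preprocess_recording(rec_mmg))
        events.append(ev)
    return env_sets, events


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
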