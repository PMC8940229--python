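"""Shared fixtures: one default simulated session reused across modules."""

import numpy as np
import pytest

from gonogo_ecog.activation import classify_trials
from gonogo_ecog.config import PipelineConfig
from gonogo_ecog.pipeline import preprocess_session
from gonogo_ecog.simulate import SimConfig, SubjectProfile, TaskConfig, simulate_session

SEED = 1234


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile("s1", 11, "right", ("left",), 0.93)


@pytest.fixture(scope="session")
def default_run(profile):
    """(session, truth) for one default 49-trial run (right grid, left hand)."""
    return simulate_session(profile, TaskConfig(), SimConfig(), seed=SEED)


@pytest.fixture(scope="session")
def preprocessed_run(default_run):
    """The default run after CAR + notch, with classified events."""
    session, truth = default_run
    session = preprocess_session(session, PipelineConfig())
    session = session.copy_with(events=classify_trials(session.events))
    return session, truth


@pytest.fixture(scope="session")
def small_run():
    """Compact 28-trial, 6-channel run for cheaper end-to-end checks."""
    prof = SubjectProfile("s2", 9, "left", ("right",), 0.95)
    task = TaskConfig(n_trials=28)
    sim = SimConfig(n_channels=6,
                    channel_rois=("motor", "motor", "ifg", "ifg",
                                  "other", "other"))
    return simulate_session(prof, task, sim, seed=SEED + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
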