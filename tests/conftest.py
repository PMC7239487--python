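"""Shared fixtures: small synthetic cohorts reused across test modules.

Expensive labelled tables are session-scoped so the generator and feature
extractor run once per pytest session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actimet.config import RunConfig
from actimet.models import ModelConfig
from actimet.pipeline import build_tables, label_session, simulate_cohort
from actimet.records import ActivitySchedule, Bout
from actimet.synthetic import (
    DEFAULT_MET_TARGETS,
    SessionParams,
    default_schedule,
    make_cohort,
    synthesize_session,
)


@pytest.fixture(scope="session")
def small_participant():
    return make_cohort(1, seed=42)[0]


@pytest.fixture(scope="session")
def small_session(small_participant):
    """One 300-s session with default noise (seed-fixed)."""
    sched = default_schedule(seed=5, session_length_s=300.0)
    return synthesize_session(small_participant, sched, seed=7)


@pytest.fixture(scope="session")
def small_hip_table(small_session):
    return label_session(small_session, "hip")


@pytest.fixture(scope="session")
def cohort6_hip_table():
    """Six subjects x 600-s sessions, hip site (shared LOSO fixture)."""
    cfg = RunConfig(seed=1, n_train=6, n_holdout=0, session_length_s=600.0)
    sessions, _ = simulate_cohort(cfg)
    return build_tables(sessions, sites=("hip",))["hip"]


@pytest.fixture(scope="session")
def train15_hip_table():
    """The stated world at full scale: 15 training subjects x 1200-s sessions.

    Shared between the parameter-recovery acceptance test and the
    planted-structure/selection invariants to amortise generation cost.
    """
    cfg = RunConfig(seed=11, n_train=15, n_holdout=0)
    sessions, _ = simulate_cohort(cfg)
    return build_tables(sessions, sites=("hip",))["hip"]


@pytest.fixture()
def seated_schedule():
    return ActivitySchedule(
        bouts=(Bout("seated", 300.0, DEFAULT_MET_TARGETS["seated"]),)
    )


@pytest.fixture()
def fast_rf_config():
    """RF config with a reduced forest for structural (non-accuracy) tests."""
    return ModelConfig(
        algorithm="rf", site="hip", k_features=10,
        hyperparameters={"n_trees": 50}, seed=3,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
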