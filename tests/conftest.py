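"""Shared fixtures: small synthetic sessions and trained detectors.

Unit tests run on reduced layouts (a few one-minute trials) to stay fast;
the acceptance tests build full 13-trial sessions of their own.
"""

from __future__ import annotations

import numpy as np
import pytest

import armpulse.beat_detection as bd
from armpulse.signal_io import SessionLayout
from armpulse.study import prepare_session
from armpulse.synthetic_data import SyntheticConfig, generate_session

SMALL_LAYOUT = SessionLayout(
    trial_count=4, trial_duration_s=60.0, window_offset_s=30.0, window_duration_s=30.0
)


@pytest.fixture(scope="session")
def small_clean_session():
    return generate_session(SyntheticConfig.clean(seed=101, layout=SMALL_LAYOUT))


@pytest.fixture(scope="session")
def small_noisy_session():
    return generate_session(SyntheticConfig(seed=102, layout=SMALL_LAYOUT))


@pytest.fixture(scope="session")
def small_noisy_session_b():
    return generate_session(SyntheticConfig(seed=103, layout=SMALL_LAYOUT))


@pytest.fixture(scope="session")
def trained_detector(small_noisy_session):
    """Detector (generator config + SVM) trained on the small noisy session."""
    prep = prepare_session(small_noisy_session)
    theta = bd.base_threshold_from_beats(prep.arm_ecg_f, prep.ref_beats.times_s)
    cfg = bd.CandidateGenConfig(base_threshold=theta)
    cand = bd.generate_candidates(prep.arm_ecg_f, cfg)
    times, X = bd.extract_feature_matrix(prep.arm_ecg_f, cand)
    y = bd.label_candidates(times, prep.ref_beats)
    model = bd.train_svm(X, y)
    return cfg, model


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
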