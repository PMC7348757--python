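"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from earesn import (
    SessionConfig,
    extract_features,
    make_subject,
    simulate_session,
)
from earesn.synthetic import Interval, LabeledRecording


@pytest.fixture(scope="session")
def small_config():
    return SessionConfig(n_runs=2, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_config):
    subject = make_subject("S01", small_config.seed)
    return simulate_session(small_config, subject)


@pytest.fixture(scope="session")
def small_features(small_recording):
    return extract_features(small_recording)


def make_flat_recording(
    signal: np.ndarray,
    fs: float = 250.0,
    state: str = "attentive",
    subject_id: str = "T",
) -> LabeledRecording:
    """A recording with one single-state interval spanning the whole signal."""
    n = signal.shape[1]
    iv = Interval(state, 0.0, n / fs, run=0, trial=0 if state == "attentive" else None,
                  start_sample=0, end_sample=n)
    labels = np.full(n, 1 if state == "attentive" else -1, dtype=np.int8)
    return LabeledRecording(
        signal=signal,
        sampling_rate_hz=fs,
        labels=labels,
        intervals=[iv],
        reaction_times=np.array([0.4]),
        subject_id=subject_id,
    )
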