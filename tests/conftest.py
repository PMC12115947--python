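"""Shared fixtures: toy epoch sets and seeded synthetic sessions.

Session-scoped fixtures hold the expensive full-length synthetic recordings;
tests that only need algebra use the small hand-built epoch sets.
"""

from __future__ import annotations

import numpy as np
import pytest

from p300baseline import (
    EpochWindow,
    NoiseModel,
    SessionSpec,
    generate_session,
    prepare_epochs,
)
from p300baseline.preprocess import Epoch, EpochSet


def make_epochset(
    arrays: dict[int, np.ndarray],
    pre_ms: float = 20.0,
    post_ms: float = 20.0,
    fs: float = 1000.0,
    target_label: int | None = None,
) -> EpochSet:
    """Build an EpochSet from per-label (n_epochs, n_samples) matrices."""
    window = EpochWindow(pre_ms, post_ms)
    epochs = []
    onset = 1000
    for label in sorted(arrays):
        for row in np.atleast_2d(arrays[label]):
            epochs.append(
                Epoch(
                    stimulus_label=label,
                    onset_sample=onset,
                    signal=np.asarray(row, dtype=float),
                    sampling_rate=fs,
                    window=window,
                )
            )
            onset += 1000
    return EpochSet(
        epochs,
        sampling_rate=fs,
        window=window,
        target_label=target_label,
        n_stimulus_types=len(arrays),
    )


@pytest.fixture(scope="session")
def default_session():
    """Full default synthetic session (900 flashes, target 3), seed 0."""
    return generate_session(SessionSpec(), NoiseModel(), seed=0)


@pytest.fixture(scope="session")
def default_epochs(default_session):
    rec, events, _ = default_session
    return prepare_epochs(rec, events)


@pytest.fixture(scope="session")
def clean_session():
    """Nearly noise-free short session: 30 presentations, tiny background."""
    spec = SessionSpec(presentations_per_stimulus=30, target_label=4)
    noise = NoiseModel(rhythm_amp_uv=1.0, broadband_rms_uv=0.5)
    return generate_session(spec, noise, seed=0)


@pytest.fixture(scope="session")
def clean_epochs(clean_session):
    rec, events, _ = clean_session
    return prepare_epochs(rec, events)
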