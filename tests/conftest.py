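"""Shared fixtures: small synthetic datasets reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from emosda import synthio


@pytest.fixture(scope="session")
def small_dataset() -> synthio.Dataset:
    """2 subjects x 3 trials, moderate effect size."""
    return synthio.generate_dataset(2, 3, seed=11, effect_size=1.0)


@pytest.fixture(scope="session")
def trimmed_small(small_dataset: synthio.Dataset) -> synthio.Dataset:
    return synthio.Dataset(
        [synthio.trim_stimulus_segment(t) for t in small_dataset.trials],
        small_dataset.n_subjects, small_dataset.n_trials_per_subject,
        seed=small_dataset.seed)


@pytest.fixture(scope="session")
def study_dataset() -> synthio.Dataset:
    """The reduced study condition: 4 subjects x 10 trials, strong effect."""
    return synthio.generate_dataset(4, 10, seed=1, effect_size=2.0)


@pytest.fixture(scope="session")
def study_trimmed(study_dataset: synthio.Dataset) -> synthio.Dataset:
    return synthio.Dataset(
        [synthio.trim_stimulus_segment(t) for t in study_dataset.trials],
        study_dataset.n_subjects, study_dataset.n_trials_per_subject,
        seed=study_dataset.seed)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
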