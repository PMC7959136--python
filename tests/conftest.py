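"""Shared fixtures: seeded scenario recordings and a small labelled corpus."""

import numpy as np
import pytest

from mandown.imu_core import compute_features
from mandown.synthetic_data import ScenarioSpec, generate, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fall_recording():
    """A forward fall ending lying still (an MDS positive)."""
    return generate(ScenarioSpec("fall_forward", post_fall="lie", seed=101))


@pytest.fixture(scope="session")
def fall_features(fall_recording):
    return compute_features(fall_recording)


@pytest.fixture(scope="session")
def lie_recording():
    return generate(ScenarioSpec("lie_still", seed=202))


@pytest.fixture(scope="session")
def walk_recording():
    return generate(ScenarioSpec("walk", seed=303))


@pytest.fixture(scope="session")
def small_corpus():
    """12 ADL + 12 MDS recordings at 100 Hz for training-path tests."""
    return generate_corpus(12, 12, seed=7, fs=100.0)
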