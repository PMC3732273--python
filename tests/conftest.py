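"""Shared fixtures: small phantom libraries reused across test modules."""

import numpy as np
import pytest

from atlasmanifold import distance_matrix, generate_library
from atlasmanifold.phantoms import latent_signal_rms

# Frozen conditions of the noisy leave-one-out study: a 30-phantom library
# with 3 latent modes, registration-error noise at 1.5x the latent signal
# rms and annotation noise at 0.5x (see docs/methods.md).
NOISY_STUDY = dict(n=30, q=3, grid_dims=(16, 16, 16), amplitude=2.5)
NOISE_FACTOR = 1.5
LABEL_NOISE_FACTOR = 0.5


def study_signal_rms() -> float:
    """Latent-signal rms of the study family (computed on a probe library)."""
    probe = generate_library(n=4, q=3, grid_dims=(16, 16, 16), amplitude=2.5, seed=1)
    return latent_signal_rms(probe)


def noisy_study_library(seed: int):
    sig = study_signal_rms()
    ps = generate_library(
        seed=seed,
        noise_rms=NOISE_FACTOR * sig,
        label_noise_rms=LABEL_NOISE_FACTOR * sig,
        **NOISY_STUDY,
    )
    return ps


@pytest.fixture(scope="session")
def phantoms12():
    """Clean 12-phantom library on a 16^3 grid (fast unit-test workhorse)."""
    return generate_library(n=12, q=3, grid_dims=(16, 16, 16), amplitude=1.5, seed=0)


@pytest.fixture(scope="session")
def phantoms30():
    """Clean 30-phantom library for embedding / extension properties."""
    return generate_library(n=30, q=3, grid_dims=(16, 16, 16), amplitude=1.5, seed=42)


@pytest.fixture(scope="session")
def distances12(phantoms12):
    return distance_matrix(phantoms12.library)


@pytest.fixture(scope="session")
def distances30(phantoms30):
    return distance_matrix(phantoms30.library)


@pytest.fixture(scope="session")
def phantoms24_truth():
    """A 24^3 truth label used by the rater-simulation studies."""
    ps = generate_library(n=4, q=3, grid_dims=(24, 24, 24), amplitude=2.5, seed=1)
    return ps.reference


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
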