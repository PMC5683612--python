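"""Shared fixtures: the Martini-like matrix and sampled umbrella windows."""

import numpy as np
import pytest

from cgkit.synthetic_fixtures import (
    TruePMF,
    martini_like_matrix,
    metropolis_umbrella_sampler,
)

#: Window centers used throughout: 12 umbrellas spanning the dimer well and tail.
UMBRELLA_CENTERS = np.linspace(0.6, 2.8, 12)
SPRING_K = 400.0  # kJ mol^-1 nm^-2


@pytest.fixture(scope="session")
def fixture_matrix():
    return martini_like_matrix()


@pytest.fixture(scope="session")
def double_well():
    return TruePMF.double_well()


@pytest.fixture(scope="session")
def umbrella_windows_small(double_well):
    """Cheap windows (4000 samples each) for module-level WHAM tests."""
    return metropolis_umbrella_sampler(
        double_well, UMBRELLA_CENTERS, k=SPRING_K, n_samples=4000, seed=7)


@pytest.fixture(scope="session")
def umbrella_windows_full(double_well):
    """Production-size windows (20000 samples each) for the recovery check."""
    return metropolis_umbrella_sampler(
        double_well, UMBRELLA_CENTERS, k=SPRING_K, n_samples=20000, seed=12345)
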