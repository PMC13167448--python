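"""Shared fixtures: a small synthetic world reused across test modules."""

import warnings

import numpy as np
import pytest

from invastack import world as w


@pytest.fixture(scope="session")
def small_world():
    """Five-scenario landscape family on a 60x60 grid (seed 7)."""
    return w.make_world(seed=7, shape=(60, 60))


@pytest.fixture(scope="session")
def current(small_world):
    return small_world["current"]


@pytest.fixture(scope="session")
def effort(current):
    return w.make_effort(seed=11, landscape=current)


@pytest.fixture(scope="session")
def species_pool(current):
    return w.make_species(seed=7, landscape=current, n_species=4)


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
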