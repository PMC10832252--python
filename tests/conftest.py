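import numpy as np
import pytest

from netpls.simulate import FixtureSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort():
    """One full-size synthetic cohort (N=836) shared across tests."""
    spec = FixtureSpec(n_subjects=836, seed=20240131)
    table, truth = generate(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap N=200 cohort for pipeline plumbing tests."""
    spec = FixtureSpec(n_subjects=200, seed=99)
    table, truth = generate(spec)
    return spec, table, truth


def centered(X):
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=0)
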