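import numpy as np
import pytest

from lfrelease.synthetic import study_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return study_fixtures()


@pytest.fixture(scope="session")
def batch1(fixtures):
    return fixtures.batches["batch1"]


@pytest.fixture(scope="session")
def batch2(fixtures):
    return fixtures.batches["batch2"]


@pytest.fixture(scope="session")
def batch3(fixtures):
    return fixtures.batches["batch3"]


@pytest.fixture(scope="session")
def weight_series(fixtures):
    return fixtures.swelling_weights


@pytest.fixture(scope="session")
def release_times():
    """Sampling times (min) resolving both the fast transfer transient and
    the slow swelling tail of the release curve."""
    return np.array([0, 0.5, 1, 1.5, 2, 3, 4, 5, 7, 10, 15, 20, 30, 45, 60,
                     120, 300, 720, 1440, 2880], dtype=float)
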