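import numpy as np
import pytest

from tinnirs.montage import build_montage
from tinnirs.schedule import build_schedule
from tinnirs.simulate import SubjectSpec, simulate_subject


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def full_schedule():
    return build_schedule(rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def resting_schedule():
    return build_schedule({"include_evoked": False}, np.random.default_rng(42))


@pytest.fixture(scope="session")
def default_subject(montage, full_schedule):
    """One default-parameter simulated subject, shared across tests."""
    rec, truth = simulate_subject(
        SubjectSpec(), montage, full_schedule, np.random.default_rng(7)
    )
    return rec, truth
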