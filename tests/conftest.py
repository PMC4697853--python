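import numpy as np
import pytest

from pknmm import (
    AnesthesiaTimeline,
    NMMParameters,
    SubjectProfile,
    run_subject,
)


@pytest.fixture(scope="session")
def subject1() -> SubjectProfile:
    return SubjectProfile(id="1", sex="male", age=39, weight=98, height=191)


@pytest.fixture(scope="session")
def short_timeline() -> AnesthesiaTimeline:
    """Compressed session used where only plumbing (not physiology) is under test."""
    return AnesthesiaTimeline(object_time=30, syringe_drop_time=60,
                              number_time=80, command_time=100)


@pytest.fixture(scope="session")
def nmm_params() -> NMMParameters:
    return NMMParameters()


@pytest.fixture(scope="session")
def subject5_result():
    """One full simulated session (the shortest subject) shared across tests."""
    profile = SubjectProfile(id="5", sex="male", age=37, weight=78, height=177)
    timeline = AnesthesiaTimeline(object_time=120, syringe_drop_time=289,
                                  number_time=360, command_time=380)
    return run_subject(profile, timeline, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
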