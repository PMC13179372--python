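import pytest
from hypothesis import settings

from abgeval import build_canonical_fixture, study_constraints

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_canonical_fixture()


@pytest.fixture(scope="session")
def constraints():
    return study_constraints()
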