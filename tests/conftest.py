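import pytest

from gutharvest.community import reference_community_profile
from gutharvest.synthetic import default_community


@pytest.fixture(scope="session")
def community_fixture():
    """Default healthy-gut fixture: archetype strains, 219 Dirichlet samples,
    and the mean-abundance community profile."""
    return default_community()


@pytest.fixture(scope="session")
def archetypes(community_fixture):
    return community_fixture.profiles


@pytest.fixture(scope="session")
def abundance_table(community_fixture):
    return community_fixture.abundance


@pytest.fixture(scope="session")
def reference_profile():
    """Community profile from the measured healthy-gut constants (29, 13)."""
    return reference_community_profile()
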