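import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def amt_fixture():
    """The grey/red-powder case evidence: MS1 voltage series + MS2 CE series."""
    from npsid.synthetic import grey_red_powder_fixture

    return grey_red_powder_fixture()


@pytest.fixture(scope="session")
def compound_db():
    from npsid.ranking_db import packaged_compound_db

    return packaged_compound_db()
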