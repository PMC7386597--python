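import pytest
from hypothesis import HealthCheck, settings

import cordflow as cf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blood():
    return cf.BloodModel()


@pytest.fixture(scope="session")
def fetal():
    return cf.FetalParams()


@pytest.fixture(scope="session")
def baseline_spec():
    return cf.CordSpec()


@pytest.fixture(scope="session")
def baseline_geometry(baseline_spec):
    return cf.build_cord_geometry(baseline_spec)


@pytest.fixture(scope="session")
def baseline_bcs(baseline_spec, blood, fetal, baseline_geometry):
    return cf.build_boundary_conditions(
        baseline_spec, blood, fetal, baseline_geometry
    )
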