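import pytest

from adjuvant_cea.outcomes import compare
from adjuvant_cea.pipeline import TwoArmModel
from adjuvant_cea.synthetic import make_fixture


@pytest.fixture(scope="session")
def fixture_config():
    """The bundled medians-calibrated two-arm configuration."""
    return make_fixture()


@pytest.fixture(scope="session")
def model(fixture_config):
    return TwoArmModel(fixture_config)


@pytest.fixture(scope="session")
def base_case(model):
    arm_i, arm_c = model.run()
    return compare(arm_i, arm_c, model.wtp)
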