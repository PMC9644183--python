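import pytest

from dietiq.config import load_config
from dietiq.core import SurveyDesign
from dietiq.synthetic import GeneratorConfig, generate, make_fixture_fct


@pytest.fixture(scope="session")
def fct():
    return make_fixture_fct()


@pytest.fixture(scope="session")
def analysis():
    return load_config()


@pytest.fixture(scope="session")
def design():
    return SurveyDesign()


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully structured two-round survey."""
    return generate(GeneratorConfig(n_psu=8, households_per_psu=6, seed=42))
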