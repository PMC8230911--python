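import pytest

from caniphen import load_panel
from caniphen.simulate import make_reference_cohorts


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def cohorts(panel):
    return make_reference_cohorts(panel)
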