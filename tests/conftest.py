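import pytest

from fragsite import simulate


@pytest.fixture(scope="session")
def panel():
    return simulate.default_panel()


@pytest.fixture(scope="session")
def profile():
    return simulate.default_profile()


#: truth masses of the default profile expressed on the panel's inter-probe
#: partition (telomeric end, six inter-probe intervals, centromeric end)
TRUTH_ON_PANEL = [0.0, 0.0, 0.10, 0.83, 0.0, 0.07, 0.0, 0.0]


@pytest.fixture(scope="session")
def truth_on_panel():
    return TRUTH_ON_PANEL
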