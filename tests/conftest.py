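import pytest

from tumortrans.params import baseline_tumor, load_solute_preset


@pytest.fixture(scope="session")
def tissue():
    return baseline_tumor()[0]


@pytest.fixture(scope="session")
def vessel():
    return baseline_tumor()[1]


@pytest.fixture(scope="session")
def solutes():
    return {mw: load_solute_preset(mw) for mw in (0.1, 3.0, 10.0, 40.0, 70.0)}
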