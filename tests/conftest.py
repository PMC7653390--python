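import pytest

from crowdcoop import ModelParams, build_reenactment_scenario


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def reenactment():
    return build_reenactment_scenario()
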