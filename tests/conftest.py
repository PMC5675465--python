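import pytest

from adenosim import ModelParameters


@pytest.fixture(scope="session")
def full_fit() -> ModelParameters:
    return ModelParameters.full_fit()


@pytest.fixture(scope="session")
def pvt_fit() -> ModelParameters:
    return ModelParameters.pvt_fit()
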