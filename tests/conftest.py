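import pytest

from pecost import calibrated_parameters, default_parameters


@pytest.fixture(scope="session")
def params():
    """Default (uncalibrated) base-case parameters."""
    return default_parameters()


@pytest.fixture(scope="session")
def calibrated(params):
    """Base-case parameters with the NICU stay resolved by calibration."""
    return calibrated_parameters(params)
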