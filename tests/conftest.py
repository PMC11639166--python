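import pytest

from tkmodel import RateParameters, ScaledParameters


@pytest.fixture
def dit_scaled() -> ScaledParameters:
    """Low-exchange configuration (DV = 0.2 < d = 2): the DIT regime."""
    return ScaledParameters(D=0.01, V=20, kappa_prime=(1.0, 1.01))


@pytest.fixture
def symmetric_rates() -> RateParameters:
    """Symmetric autocatalysis with deliberately unequal inflows."""
    return RateParameters(d=2, kappa=(0.05, 0.05), lam=(0.1, 0.3), delta=0.01)


@pytest.fixture
def asymmetric_rates() -> RateParameters:
    """Asymmetric rates with unequal inflows; exercises the general closed form."""
    return RateParameters(d=2, kappa=(0.05, 0.055), lam=(0.1, 0.3), delta=0.01)
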