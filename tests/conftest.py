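import pytest

from bedbugsim import (
    CostRates,
    Parameters,
    calibrated_system,
    disclosure_run,
)


@pytest.fixture(scope="session")
def default_params():
    """Point estimates: p=5%, s=0.5, 1/gamma=6 mo, k=0.3, b=1.3, m=0.5,
    n=6, D=1 y, N=1000."""
    return Parameters()


@pytest.fixture(scope="session")
def calibrated_default(default_params):
    """Default parameters with beta calibrated to the 5% baseline, plus the
    endemic equilibrium used as the initial condition everywhere."""
    return calibrated_system(params=default_params)


@pytest.fixture(scope="session")
def default_run():
    """The headline policy experiment: disclosure vs. no-disclosure from the
    calibrated 5% equilibrium, 20 years, Table-rate costs."""
    return disclosure_run(params=Parameters(), rates=CostRates(), horizon=20)
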