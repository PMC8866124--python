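import numpy as np
import pytest

from ringflip.exchange import CpmgSchedule, ExchangeParameters, SpinProbe


@pytest.fixture()
def wildtype_params() -> ExchangeParameters:
    """Published-fit-like two-site parameters for a single 15N spin."""
    return ExchangeParameters(2600.0, 0.028, {("R1", "15N"): 3.0})


@pytest.fixture()
def nitrogen_spin() -> SpinProbe:
    return SpinProbe("R1", "15N", {600.0: 8.0, 850.0: 9.5}, r1=1.2)


@pytest.fixture()
def nitrogen_cpmg_600() -> CpmgSchedule:
    nu = np.array([31.25, 62.5, 125.0, 187.5, 250.0, 312.5, 375.0,
                   500.0, 625.0, 750.0, 875.0, 1000.0])
    return CpmgSchedule(0.032, nu, 600.0)
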