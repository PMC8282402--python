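import numpy as np
import pytest

import ecgvol as ev


@pytest.fixture(scope="session")
def garch11_sample():
    """A moderately long GARCH(1,1) draw shared by several tests."""
    orders = ev.VolatilityOrders("GARCH", 1, 1)
    params = ev.VolatilityParams(alpha0=0.1, alpha=[0.2], beta=[0.7])
    sim = ev.simulate_volatility(orders, params, 6000, seed=1234)
    return sim["y"]


@pytest.fixture(scope="session")
def apnea_segments():
    """Ten apnea-like surrogate segments with their truth manifest."""
    spec = ev.ScenarioSpec(regime="apnea_like", n_segments=10, seed=77)
    return ev.make_ecg_like(spec)
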