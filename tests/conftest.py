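import numpy as np
import pytest

from rotorlab.scenarios import scenario_s1s2_spiral


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def s1s2_run():
    """One scaled S1S2 run shared by the spiral/tip/partition tests.

    Returns (simulation, result); the simulation exposes the fired trigger.
    """
    scen = scenario_s1s2_spiral(scaled=True)
    sim = scen.build()
    result = sim.run()
    return sim, result
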