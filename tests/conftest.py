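import numpy as np
import pytest

from tobaccohia import SyntheticParams, generate_bundle, run_simulation
from tobaccohia.scenario import Scenario


@pytest.fixture(scope="session")
def params1():
    return SyntheticParams(seed=1)


@pytest.fixture(scope="session")
def bundle1(params1):
    """Default synthetic country bundle, seed 1."""
    return generate_bundle(params1)


@pytest.fixture(scope="session")
def ref_traj(bundle1):
    """Reference (no price change) 40-year trajectory on the seed-1 bundle."""
    return run_simulation(bundle1)


@pytest.fixture(scope="session")
def traj_by_price(bundle1, ref_traj):
    """Trajectories for the full price sweep {0,5,10,20,30,40,50}%."""
    out = {0.0: ref_traj}
    for p in (5.0, 10.0, 20.0, 30.0, 40.0, 50.0):
        out[p] = run_simulation(bundle1, Scenario(price_increase_percent=p))
    return out


@pytest.fixture
def zero_rate_bundle(bundle1):
    """Seed-1 bundle with every transition, incidence and death switched off."""
    b = bundle1.copy()
    b.transitions.initiation[:] = 0.0
    b.transitions.cessation[:] = 0.0
    b.transitions.restart[:] = 0.0
    b.disease.copd_incidence[:] = 0.0
    b.mortality.all_cause[:] = 0.0
    b.demographics.newborns[:] = 0.0
    return b
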