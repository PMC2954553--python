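import pytest
from hypothesis import settings

from nicopbpk.parameters import (
    human_params,
    rat_cotinine_params,
    rat_nicotine_params,
)
from nicopbpk import pbpk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rat():
    """(nicotine, cotinine, physiology, regimen) for the reference rat study."""
    nic, phys, regimen = rat_nicotine_params()
    return nic, rat_cotinine_params(), phys, regimen


@pytest.fixture(scope="session")
def human():
    """(nicotine, cotinine, physiology, regimen) for the reference human model."""
    return human_params()


@pytest.fixture(scope="session")
def human_noael_sim(human):
    nic, cot, phys, regimen = human
    return pbpk.simulate(nic, cot, phys, regimen, t_end=48.0)


@pytest.fixture(scope="session")
def human_smoker_sim(human):
    nic, cot, phys, regimen = human
    smoker = regimen.model_copy(update={"dose_amount": 43400.0})
    return pbpk.simulate(nic, cot, phys, smoker, t_end=48.0)


@pytest.fixture(scope="session")
def rat_noael_sim(rat):
    nic, cot, phys, regimen = rat
    return pbpk.simulate(nic, cot, phys, regimen, t_end=14 * 24.0)
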