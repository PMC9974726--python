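import numpy as np
import pytest

from gfuncsim import (
    BasicGrowthModel,
    BasicGrowthParams,
    CommunityState,
    CompetitionModel,
    CompetitionParams,
    DrugParams,
    DrugResistanceModel,
)

# control configuration used throughout: x0=10, v0=3, K_m=100, r=0.25,
# sigma_k2=12.5, trait evolvability k=0.2


@pytest.fixture(scope="session")
def control_params():
    return BasicGrowthParams(r=0.25, K_m=100.0, sigma_k2=12.5)


@pytest.fixture(scope="session")
def basic_model(control_params):
    return BasicGrowthModel(control_params)


@pytest.fixture(scope="session")
def narrow_competition(control_params):
    return CompetitionModel(CompetitionParams(base=control_params, sigma_a2=2.0))


@pytest.fixture(scope="session")
def broad_competition(control_params):
    return CompetitionModel(CompetitionParams(base=control_params, sigma_a2=50.0))


@pytest.fixture(scope="session")
def drug_params(control_params):
    return DrugParams(base=control_params, s_m=0.2, u_opt=0.0, sigma_t2=0.8, time_G=600.0)


@pytest.fixture(scope="session")
def drug_model(drug_params):
    return DrugResistanceModel(drug_params)


@pytest.fixture
def control_community():
    return CommunityState.from_arrays([3.0], [10.0], [0.2])


@pytest.fixture
def two_clone_community():
    return CommunityState.from_arrays([3.0, -3.0], [10.0, 10.0], [0.2, 0.2])
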