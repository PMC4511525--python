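import numpy as np
import pytest

from curliswitch import logic_model as lm
from curliswitch.kinetic_model import KineticParameters
from curliswitch.synthetic_data import ANCHOR_BISTABLE_SETS


@pytest.fixture(scope="session")
def anchors() -> list[KineticParameters]:
    return [KineticParameters.from_dict(d) for d in ANCHOR_BISTABLE_SETS]


@pytest.fixture(scope="session")
def bistable_p(anchors) -> KineticParameters:
    return anchors[0]


@pytest.fixture(scope="session")
def candidate_models():
    return lm.build_candidate_models()


@pytest.fixture(scope="session")
def feasible_models(candidate_models):
    return lm.filter_models(candidate_models, lm.build_constraints("conservative"))


@pytest.fixture(scope="session")
def small_monostable_p() -> KineticParameters:
    """Hand-constructed monostable set with small copy numbers, cheap to
    simulate; used for SSA/ODE agreement checks."""
    return KineticParameters(
        Vmax1=50.0,
        Vmax2=100.0,
        Km_YhjH=500.0,
        Km_YciR=500.0,
        Kd_YciR=500.0,
        Ki_YegE=1000.0,
        k_YdaMact=100.0,
        k_YciRact=50.0,
        Kd_YdaM=500.0,
        Kd_polymer_YdaM=100.0,
        YciRtot=40.0,
        YdaMtot=40.0,
        k_YciRde=1000.0,
        k_YdaMde=1000.0,
    )
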