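from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import pytest

from diplothermo import EnergyParams, SystemConfig


@pytest.fixture(scope="session")
def params() -> EnergyParams:
    """Default energies: dG_folding_wt=-2, dG_binding_wt=-5, 37 degC."""
    return EnergyParams()


@pytest.fixture(scope="session")
def ratio1() -> SystemConfig:
    return SystemConfig(ligand_ratio=1.0)
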