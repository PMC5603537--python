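import numpy as np
import pytest

from methanocosm import PartitionFactors, ScenarioConfig, Substrate
from methanocosm.carbonate import BottleConfig
from methanocosm.stoichiometry import SUBSTRATES


@pytest.fixture
def glucose() -> Substrate:
    return SUBSTRATES["glucose"]


@pytest.fixture
def factors() -> PartitionFactors:
    return PartitionFactors(fs=0.2)


@pytest.fixture
def glucose_bottle(glucose) -> BottleConfig:
    """10 mM glucose in 100 mL liquid / 60 mL headspace, 1 g/L NaHCO3."""
    return BottleConfig(
        substrate=glucose,
        substrate_dose_mol=1e-3,
        liquid_volume_l=0.1,
        headspace_volume_l=0.06,
        buffer_mg_per_l=1000.0,
    )


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    """Trimmed scenario (three treatments) to keep pipeline tests quick."""
    from methanocosm.synthetic import TABLE1_PARAMS

    keep = {k: TABLE1_PARAMS[k] for k in ("glucose", "xylose", "cellobiose")}
    return ScenarioConfig(treatments=keep, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
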