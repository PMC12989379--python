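import numpy as np
import pandas as pd
import pytest

from omicnet.io import ClinicalTable, OmicsLayer
from omicnet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast recurrence-design cohort with planted effects and modules."""
    return SimulationConfig(
        n_per_group=(35, 55),
        n_features={"methylation": 80, "rna": 80, "protein": 80},
        n_diff={"methylation": 10, "rna": 10, "protein": 10},
        n_modules=3,
        module_size=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def toy_layer() -> OmicsLayer:
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["g1", "g2", "g3"],
        columns=["A", "B", "C", "D"],
    )
    return OmicsLayer(layer_name="rna", values=values)


@pytest.fixture
def toy_clinical() -> ClinicalTable:
    return ClinicalTable(
        table=pd.DataFrame(
            {"recurrence": ["no", "no", "yes", "yes"], "grade": [1, 2, 2, 3]},
            index=["A", "B", "C", "D"],
        )
    )
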