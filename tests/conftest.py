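import numpy as np
import pandas as pd
import pytest

from glvdriver import CommunityModel, SimulationConfig, generate_dataset
from glvdriver.preprocess import AbundanceTable


@pytest.fixture(scope="session")
def logistic_model():
    """Single-taxon logistic community: alpha=0.2, beta=-0.001, K=200."""
    return CommunityModel(("sp1",), np.array([0.2]), np.array([[-0.001]]))


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset reused across tests (n=2, p=3, m=8)."""
    return generate_dataset(
        SimulationConfig(n=2, p=3, m=8, pi=0.8, phi=1.0, seed=7)
    )


@pytest.fixture()
def toy_table():
    """3-taxon, 4-sample abundance table with two subjects."""
    values = pd.DataFrame(
        {
            "A_T0": [10.0, 0.0, 5.0],
            "A_T2": [20.0, 1.0, 0.0],
            "B_T0": [0.0, 2.0, 7.0],
            "B_T3": [40.0, 0.0, 9.0],
        },
        index=pd.Index(["taxA", "taxB", "taxC"], name="taxon"),
    )
    meta = pd.DataFrame(
        {
            "subject": ["A", "A", "B", "B"],
            "time": [0.0, 2.0, 0.0, 3.0],
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return AbundanceTable(values=values, meta=meta)
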