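import numpy as np
import pandas as pd
import pytest

from proteoalloc.model import SampleDesign
from proteoalloc.simulate import default_truth, simulate_dataset


@pytest.fixture
def two_by_three_design() -> SampleDesign:
    """Two conditions x three replicates, the canonical small design."""
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["A_r1", "A_r2", "A_r3", "B_r1", "B_r2", "B_r3"],
                "condition": ["A"] * 3 + ["B"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )
    )


@pytest.fixture
def small_matrix(two_by_three_design) -> pd.DataFrame:
    """A complete 4-protein x 6-sample matrix of raw abundances."""
    rng = np.random.default_rng(7)
    values = np.exp2(rng.normal(20, 2, size=(4, 6)))
    return pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(4)],
        columns=two_by_three_design.sample_ids,
    )


@pytest.fixture(scope="session")
def hexadecane_sim():
    """One simulated hexadecane-scenario dataset, shared across tests."""
    return simulate_dataset(default_truth("hexadecane", seed=2))


@pytest.fixture(scope="session")
def null_sim():
    """One simulated null-scenario dataset, shared across tests."""
    return simulate_dataset(default_truth("null", seed=5))
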