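import numpy as np
import pandas as pd
import pytest

from lcmarray import simulate
from lcmarray.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def gfcr_design():
    return simulate.generate_design(
        ("ileum", "colon"), ("tip", "crypt"), ("GF", "CR"), 5, seed=0
    )


@pytest.fixture(scope="session")
def timecourse_design():
    return simulate.generate_design(
        ("ileum", "colon"), ("tip", "crypt"), ("0", "1", "3", "5", "7"), 3, seed=0
    )


@pytest.fixture(scope="session")
def small_synthetic(gfcr_design):
    """2,000-gene GF/CR matrix with planted truth, shared across tests."""
    return simulate.simulate_expression(gfcr_design, n_genes=2000, seed=11)


@pytest.fixture
def toy_matrix():
    data = pd.DataFrame(
        np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data)
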