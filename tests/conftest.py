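import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sphinks as sp
from sphinks.simulate import CohortSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def smoke_cohort():
    """One deterministic smoke-scale cohort shared across tests."""
    spec = sp.default_specs()["smoke"]
    return sp.generate_cohort(spec)


@pytest.fixture(scope="session")
def smoke_pipeline(smoke_cohort):
    """Full pipeline result on the smoke cohort (small ensemble)."""
    proteome, phospho, labels, truth = smoke_cohort
    res = sp.run_pipeline(proteome, phospho, truth.revealed_prior,
                          list(proteome.features), labels=labels,
                          n_bags=15, n_bins=10, seed=7)
    return res, truth, labels, proteome, phospho


@pytest.fixture
def tiny_matrix():
    """3 features x 4 samples complete log2 matrix."""
    df = pd.DataFrame(
        np.array([[1.0, 2.0, 3.0, 4.0],
                  [2.0, 1.0, 4.0, 3.0],
                  [0.5, 0.5, 0.5, 0.5]]),
        index=["A_S1", "B_T2", "C_Y3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return sp.AbundanceMatrix(df, scale="log2")


def make_matrix(values, features=None, samples=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return sp.AbundanceMatrix(pd.DataFrame(values, index=features, columns=samples),
                              scale=scale)
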