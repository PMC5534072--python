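import numpy as np
import pandas as pd
import pytest

from brainomics import simulate
from brainomics.io import CountMatrix, SampleTable


@pytest.fixture(scope="session")
def null_cohort():
    """A small cohort with no planted effects (shared across read-only tests)."""
    cfg = simulate.CohortConfig(n_genes=600, n_per_group=12, n_metabolites=40)
    return simulate.make_cohort(cfg, seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        {"s1": [3, 1], "s2": [0, 7]}, index=pd.Index(["gA", "gB"], name="gene_id")
    )
    return CountMatrix(df)


def make_sample_table(n_per_group, diagnoses=("CTL", "SZ"), seed=0):
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for dx in diagnoses:
        for i in range(n_per_group):
            ids.append(f"{dx}_{i}")
            rows.append(
                {
                    "diagnosis": dx,
                    "region": "AnCg",
                    "age": float(rng.uniform(30, 70)),
                    "pH": float(rng.uniform(6.5, 7.1)),
                    "PMI": float(rng.uniform(5, 35)),
                    "PRUA": float(rng.uniform(0.7, 0.95)),
                }
            )
    return SampleTable(pd.DataFrame(rows, index=pd.Index(ids, name="sample_id")))
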