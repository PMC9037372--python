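import numpy as np
import pandas as pd
import pytest

from exlr.core_data import ExpressionMatrix
from exlr.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 600-gene cohort with 10 planted CRC-up genes, shared by tests."""
    cfg = SimulationConfig(
        n_genes=600, n_crc=20, n_cra=10, n_healthy=20, n_planted_up=10, seed=11
    )
    counts, annotation, design, truth = simulate_cohort(cfg)
    return counts, annotation, design, truth


@pytest.fixture
def toy_annotation():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "symbol": ["A", "B", "C"],
            "biotype": ["protein_coding", "lncRNA", "protein_coding"],
            "length_bp": [1000, 2000, 500],
        }
    )


def make_matrix(values, unit="counts", genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), unit)
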