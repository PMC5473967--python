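import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ribocycle import SimulationConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ribocycle.dataio import CountMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """A 200-gene simulated dataset shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_genes=200)
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_counts():
    """Three genes, four samples, one full timepoint pair per organ."""
    cols = ["kidney_RNA_ZT00_rep1", "kidney_RNA_ZT00_rep2",
            "liver_RNA_ZT00_rep1", "liver_RNA_ZT00_rep2"]
    counts = pd.DataFrame(
        [[10, 12, 9, 11], [100, 90, 110, 95], [3, 4, 2, 5]],
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"), columns=cols)
    lengths = pd.DataFrame(
        {"utr5_len": [100, 150, 80], "cds_len": [900, 1200, 300],
         "utr3_len": [200, 100, 150]}, index=counts.index)
    return CountMatrix(counts=counts, lengths=lengths)


def make_te_table(values: np.ndarray, organ: str) -> pd.DataFrame:
    """Gene x 24-sample TE table on the standard 12-ZT, 2-replicate grid."""
    cols = [f"{organ}_TE_ZT{tp:02d}_rep{rep}"
            for tp in range(0, 24, 2) for rep in (1, 2)]
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, columns=cols,
                        index=[f"g{i:04d}" for i in range(values.shape[0])])
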