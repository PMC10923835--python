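import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cassidi import (
    CountMatrix,
    MarkerRecord,
    SyntheticConfig,
    simulate_paired_datasets,
)


def make_record(
    gene: str,
    cluster: str = "0",
    avg_log_fc: float = 1.0,
    pct_in: float = 1.0,
    pct_bg: float = 1.0,
    p_adj: float = 0.01,
) -> MarkerRecord:
    return MarkerRecord(
        gene=gene,
        cluster=cluster,
        avg_log_fc=avg_log_fc,
        pct_in=pct_in,
        pct_bg=pct_bg,
        p_val=p_adj / 2,
        p_adj=p_adj,
    )


@pytest.fixture(scope="session")
def two_pop():
    """Two planted populations per condition, 300 cells each, 8-fold markers."""
    cfg = SyntheticConfig(
        k_shared=2,
        k_unique_a=0,
        k_unique_b=0,
        cells_per_cluster=300,
        n_genes=500,
        markers_per_cluster=50,
        fold_change=8.0,
        seed=3,
    )
    return simulate_paired_datasets(cfg)


@pytest.fixture(scope="session")
def five_pop():
    cfg = SyntheticConfig(
        k_shared=5,
        k_unique_a=0,
        k_unique_b=0,
        cells_per_cluster=150,
        n_genes=600,
        markers_per_cluster=40,
        fold_change=8.0,
        seed=4,
    )
    return simulate_paired_datasets(cfg)


@pytest.fixture(scope="session")
def default_pair():
    """The default study condition: 4 shared + 1 B-unique cluster."""
    return simulate_paired_datasets(SyntheticConfig(seed=7))


@pytest.fixture()
def small_counts():
    """A deterministic 20-gene x 60-cell matrix with one planted cluster."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(1.0, size=(20, 60))
    counts[:5, :20] += rng.poisson(6.0, size=(5, 20))  # genes 0-4 mark cells 0-19
    labels = np.array(["1"] * 20 + ["0"] * 40)
    cm = CountMatrix(
        gene_ids=[f"g{i}" for i in range(20)],
        cell_ids=[f"c{i}" for i in range(60)],
        counts=sp.csr_matrix(counts),
        dataset_id="small",
    )
    return cm, labels
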