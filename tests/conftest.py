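import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pblmm.pseudobulk import CellCounts, ClusterCounts, PseudobulkSet


@pytest.fixture()
def toy_cells() -> CellCounts:
    """6 cells, 3 genes, 2 samples x 2 clusters (one pair absent)."""
    counts = np.array(
        [
            [1, 2, 0],
            [3, 4, 1],
            [0, 1, 5],
            [2, 0, 0],
            [1, 1, 1],
            [0, 0, 2],
        ]
    )
    return CellCounts(
        counts=sp.csr_matrix(counts),
        cell_sample=np.array(["A", "A", "B", "B", "A", "B"], dtype=object),
        cell_cluster=np.array(["k1", "k1", "k1", "k1", "k2", "k2"], dtype=object),
        gene_ids=np.array(["g1", "g2", "g3"], dtype=object),
    )


@pytest.fixture()
def toy_pb() -> PseudobulkSet:
    samples = pd.Index(["A", "B", "C", "D"], name="sample")
    genes = pd.Index([f"g{i}" for i in range(5)], name="gene")
    Y = pd.DataFrame(
        np.array(
            [
                [10, 0, 5, 100, 1],
                [20, 0, 6, 90, 0],
                [15, 0, 0, 80, 2],
                [12, 5, 7, 70, 0],
            ]
        ),
        index=samples,
        columns=genes,
    )
    n = pd.Series([9, 10, 50, 30], index=samples, name="n_cells")
    meta = pd.DataFrame({"diagnosis": ["case", "control", "case", "control"]}, index=samples)
    return PseudobulkSet(data={"k": ClusterCounts(Y, n)}, sample_meta=meta)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated dataset shared across tests (read-only)."""
    from pblmm.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_subjects=20,
        subjects_per_batch=5,
        n_genes=250,
        n_cells_per_subject=50,
        sigma2_subject=0.05,
        sigma2_batch=0.05,
        seed=11,
    )
    cells, meta = simulate_dataset(cfg)
    return cfg, cells, meta
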