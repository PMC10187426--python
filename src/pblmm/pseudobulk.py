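"""Pseudobulk aggregation, filtering and log2-CPM normalization.

Single-cell counts are summed per (cell cluster, sample) into pseudobulk
profiles that are then analyzed like bulk RNA-seq: samples with too few
cells are dropped, weakly expressed genes are filtered per cluster, and the
retained counts are library-size normalized to log2 counts per million.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellCounts",
    "ClusterCounts",
    "PseudobulkSet",
    "LogExpression",
    "aggregate",
    "filter_samples",
    "filter_genes",
    "log2cpm",
]


@dataclass
class CellCounts:
    """Sparse cell x gene integer counts with per-cell sample and cluster labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows and genes in columns.
        Stored as CSR; dense input is converted.
    cell_sample
        Sample (specimen/donor-replicate) label per cell.
    cell_cluster
        Cell cluster (cell type) label per cell.
    gene_ids
        Unique gene identifier per column.
    """

    counts: sp.csr_matrix
    cell_sample: np.ndarray
    cell_cluster: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.cell_sample = np.asarray(self.cell_sample, dtype=object)
        self.cell_cluster = np.asarray(self.cell_cluster, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_sample) != n_cells or len(self.cell_cluster) != n_cells:
            raise ValueError("cell labels must have one entry per cell")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids must have one entry per gene")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and np.abs(data - np.round(data)).max() > 1e-6:
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        missing = _missing_label_mask(self.cell_sample) | _missing_label_mask(
            self.cell_cluster
        )
        if missing.any():
            idx = np.flatnonzero(missing)[:20]
            raise ValueError(
                f"{missing.sum()} cells have missing sample or cluster labels "
                f"(first offending cell indices: {idx.tolist()})"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def iter_blocks(self, block_size: int):
        """Yield ``(row_slice, csr_block)`` over blocks of cells.

        The matrix is accessed one block of cells (all genes) at a time so
        that aggregation never materializes more than one block.
        """
        if block_size < 1:
            raise ValueError("block_size must be >= 1")
        for start in range(0, self.n_cells, block_size):
            stop = min(start + block_size, self.n_cells)
            yield slice(start, stop), self.counts[start:stop]


def _missing_label_mask(labels: np.ndarray) -> np.ndarray:
    out = np.zeros(len(labels), dtype=bool)
    for i, v in enumerate(labels):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            out[i] = True
    return out


@dataclass
class ClusterCounts:
    """Pseudobulk counts for one cell cluster: samples x genes plus cell counts."""

    Y: pd.DataFrame  # samples x genes, integer sums
    n: pd.Series  # cells per sample in this cluster

    def copy(self) -> "ClusterCounts":
        return ClusterCounts(self.Y.copy(), self.n.copy())


@dataclass
class PseudobulkSet:
    """Per-cluster pseudobulk counts with shared sample metadata.

    ``data`` maps cluster name to :class:`ClusterCounts`; ``sample_meta`` is
    keyed by sample id and carries the covariates used downstream.
    ``dropped`` records clusters/samples removed by filters.
    """

    data: dict[str, ClusterCounts]
    sample_meta: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    @property
    def clusters(self) -> list[str]:
        return list(self.data.keys())

    def total_counts(self) -> int:
        return int(sum(c.Y.to_numpy().sum() for c in self.data.values()))


@dataclass
class LogExpression:
    """log2-CPM matrix (samples x genes) for one cluster with its library sizes."""

    E: pd.DataFrame
    lib_size: pd.Series

    @property
    def samples(self) -> pd.Index:
        return self.E.index

    @property
    def genes(self) -> pd.Index:
        return self.E.columns


def aggregate(
    cells: CellCounts,
    sample_meta: pd.DataFrame | None = None,
    block_size: int = 50_000,
) -> PseudobulkSet:
    """Sum cell-level counts into per-(cluster, sample) pseudobulk.

    Cells are processed in blocks of at most ``block_size`` rows; within a
    block a sparse indicator matrix maps cells to (cluster, sample) pairs so
    the accumulator is a dense pairs x genes array. The result is exactly
    independent of ``block_size`` (integer sums are associative).

    Cluster x sample pairs with zero cells are absent from the result rather
    than zero-filled.
    """
    if cells.n_cells == 0:
        raise ValueError("no cells to aggregate")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    pairs = pd.MultiIndex.from_arrays(
        [cells.cell_cluster, cells.cell_sample], names=["cluster", "sample"]
    )
    uniq = pairs.unique().sortlevel()[0]
    code = uniq.get_indexer(pairs)
    n_pairs = len(uniq)

    acc = np.zeros((n_pairs, cells.n_genes), dtype=np.int64)
    n_cells_per_pair = np.bincount(code, minlength=n_pairs)
    for rows, block in cells.iter_blocks(block_size):
        bcode = code[rows]
        ind = sp.csr_matrix(
            (np.ones(len(bcode), dtype=np.int64), (bcode, np.arange(len(bcode)))),
            shape=(n_pairs, len(bcode)),
        )
        acc += np.asarray((ind @ block).todense())

    data: dict[str, ClusterCounts] = {}
    for cluster in uniq.get_level_values("cluster").unique():
        mask = uniq.get_level_values("cluster") == cluster
        samples = pd.Index(uniq.get_level_values("sample")[mask], name="sample")
        Y = pd.DataFrame(acc[mask], index=samples, columns=pd.Index(cells.gene_ids, name="gene"))
        n = pd.Series(n_cells_per_pair[mask], index=samples, name="n_cells")
        data[str(cluster)] = ClusterCounts(Y, n)

    if sample_meta is None:
        all_samples = pd.Index(sorted(set(cells.cell_sample)), name="sample")
        sample_meta = pd.DataFrame(index=all_samples)
    else:
        sample_meta = sample_meta.copy()
        seen = set(cells.cell_sample)
        unknown = seen - set(sample_meta.index)
        if unknown:
            raise ValueError(f"cells reference samples absent from sample_meta: {sorted(unknown)[:10]}")
    return PseudobulkSet(data=data, sample_meta=sample_meta)


def filter_samples(pb: PseudobulkSet, min_cells: int = 10) -> PseudobulkSet:
    """Drop, within each cluster, samples observed with fewer than ``min_cells`` cells.

    Clusters retaining fewer than two samples are removed entirely and listed
    in the returned ``dropped`` report.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    data: dict[str, ClusterCounts] = {}
    dropped = list(pb.dropped)
    for cluster, cc in pb.data.items():
        keep = cc.n >= min_cells
        n_drop = int((~keep).sum())
        if n_drop:
            dropped.append(
                f"cluster {cluster}: dropped {n_drop} sample(s) with < {min_cells} cells"
            )
        if keep.sum() < 2:
            dropped.append(f"cluster {cluster}: removed (< 2 samples with >= {min_cells} cells)")
            continue
        data[cluster] = ClusterCounts(cc.Y.loc[keep], cc.n.loc[keep])
    return PseudobulkSet(data=data, sample_meta=pb.sample_meta, dropped=dropped)


def filter_genes(
    pb: PseudobulkSet, min_count: float = 5, min_prop: float = 0.3
) -> PseudobulkSet:
    """Retain, per cluster, genes with count >= ``min_count`` in >= ``min_prop`` of samples.

    Gene sets may differ across clusters; the filter is applied independently
    within each cluster's retained samples.
    """
    if not 0 <= min_prop <= 1:
        raise ValueError("min_prop must be in [0, 1]")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    data: dict[str, ClusterCounts] = {}
    for cluster, cc in pb.data.items():
        prop = (cc.Y >= min_count).mean(axis=0)
        keep = prop >= min_prop
        data[cluster] = ClusterCounts(cc.Y.loc[:, keep], cc.n.copy())
    return PseudobulkSet(data=data, sample_meta=pb.sample_meta, dropped=list(pb.dropped))


def log2cpm(cc: ClusterCounts) -> LogExpression:
    """Transform one cluster's pseudobulk counts to log2 counts per million.

    E[i, g] = log2((Y[i, g] + 0.5) / (lib_size[i] + 1) * 1e6) with
    lib_size[i] the column sum of the (already gene-filtered) count matrix.
    """
    Y = cc.Y.to_numpy(dtype=float)
    lib = Y.sum(axis=1)
    zero = lib <= 0
    if zero.any():
        bad = cc.Y.index[zero].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    E = np.log2((Y + 0.5) / (lib[:, None] + 1.0) * 1e6)
    return LogExpression(
        E=pd.DataFrame(E, index=cc.Y.index, columns=cc.Y.columns),
        lib_size=pd.Series(lib, index=cc.Y.index, name="lib_size"),
    )
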