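"""Readers and writers for the standard on-disk formats.

Inputs: H5AD (counts in X or a named layer; obs columns give the sample and
cluster labels) or MatrixMarket plus two TSVs (cell metadata, gene ids).
The H5AD reader opens the file in backed mode so cells can be streamed in
blocks without materializing the full matrix. Outputs are plain TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pseudobulk import CellCounts, PseudobulkSet

__all__ = [
    "read_h5ad_cells",
    "read_mtx_cells",
    "write_h5ad",
    "write_pseudobulk",
    "read_pseudobulk",
]


def read_h5ad_cells(
    path,
    sample_col: str,
    cluster_col: str,
    layer: str | None = None,
    backed: bool = True,
):
    """Load cell counts and sample metadata from an H5AD file.

    Returns ``(CellCounts, sample_meta)`` where sample_meta collapses obs
    columns that are constant within sample. With ``backed=True`` the count
    matrix is read block-wise (all genes, chunks of cells) instead of in one
    piece; the assembled CSR is still returned in memory, which is
    appropriate for the pseudobulk-scale analyses here.
    """
    import anndata as ad

    adata = ad.read_h5ad(path, backed="r" if backed else None)
    obs = adata.obs
    for col in (sample_col, cluster_col):
        if col not in obs.columns:
            raise ValueError(f"obs column {col!r} not found in {path}")
    X = adata.layers[layer] if layer else adata.X
    n = adata.n_obs
    blocks = []
    step = 100_000
    for start in range(0, n, step):
        chunk = X[start : min(start + step, n)]
        if sp.issparse(chunk):
            blocks.append(sp.csr_matrix(chunk))
        else:
            blocks.append(sp.csr_matrix(np.asarray(chunk)))
    counts = sp.vstack(blocks).tocsr() if blocks else sp.csr_matrix((0, adata.n_vars))
    cells = CellCounts(
        counts=counts,
        cell_sample=obs[sample_col].astype(str).to_numpy(dtype=object),
        cell_cluster=obs[cluster_col].astype(str).to_numpy(dtype=object),
        gene_ids=adata.var_names.to_numpy(dtype=object),
    )
    sample_meta = _collapse_sample_meta(obs, sample_col)
    if isinstance(adata, ad.AnnData) and adata.isbacked:
        adata.file.close()
    return cells, sample_meta


def _collapse_sample_meta(obs: pd.DataFrame, sample_col: str) -> pd.DataFrame:
    keep = [
        c
        for c in obs.columns
        if c != sample_col and obs.groupby(obs[sample_col].astype(str))[c].nunique().max() <= 1
    ]
    meta = (
        obs.assign(**{sample_col: obs[sample_col].astype(str)})
        .groupby(sample_col)[keep]
        .first()
    )
    meta.index.name = "sample"
    return meta


def read_mtx_cells(mtx_path, cell_meta_path, gene_path, sample_col: str, cluster_col: str):
    """Load cell counts from MatrixMarket (cells x genes) + cell metadata TSV + gene TSV."""
    from scipy.io import mmread

    counts = sp.csr_matrix(mmread(mtx_path))
    cell_meta = pd.read_csv(cell_meta_path, sep="\t")
    genes = pd.read_csv(gene_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    for col in (sample_col, cluster_col):
        if col not in cell_meta.columns:
            raise ValueError(f"column {col!r} not found in {cell_meta_path}")
    if len(cell_meta) != counts.shape[0]:
        raise ValueError("cell metadata rows do not match matrix rows")
    cells = CellCounts(
        counts=counts,
        cell_sample=cell_meta[sample_col].astype(str).to_numpy(dtype=object),
        cell_cluster=cell_meta[cluster_col].astype(str).to_numpy(dtype=object),
        gene_ids=genes,
    )
    sample_meta = _collapse_sample_meta(cell_meta, sample_col)
    return cells, sample_meta


def write_h5ad(path, cells: CellCounts, sample_meta: pd.DataFrame, sample_col="sample", cluster_col="cluster"):
    """Write cell counts (plus per-cell sample/cluster labels) as H5AD."""
    import anndata as ad

    obs = pd.DataFrame(
        {
            sample_col: pd.Series(cells.cell_sample, dtype=str),
            cluster_col: pd.Series(cells.cell_cluster, dtype=str),
        }
    )
    obs.index = [f"cell{i}" for i in range(cells.n_cells)]
    meta = sample_meta.astype(str)
    for col in meta.columns:
        obs[col] = meta.loc[obs[sample_col], col].to_numpy()
    adata = ad.AnnData(
        X=cells.counts.astype(np.float32),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(cells.gene_ids.astype(str), name="gene")),
    )
    adata.write_h5ad(Path(path))


def write_pseudobulk(pb: PseudobulkSet, outdir) -> None:
    """Write one genes x samples count TSV per cluster plus a samples TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cluster, cc in pb.data.items():
        cc.Y.T.to_csv(outdir / f"pseudobulk_{cluster}.tsv", sep="\t")
        samples = pb.sample_meta.loc[cc.Y.index].copy()
        samples.insert(0, "n_cells", cc.n)
        samples.to_csv(outdir / f"samples_{cluster}.tsv", sep="\t")
    if pb.dropped:
        (outdir / "dropped.txt").write_text("\n".join(pb.dropped) + "\n")


def read_pseudobulk(outdir) -> PseudobulkSet:
    """Read back a pseudobulk directory written by :func:`write_pseudobulk`."""
    from .pseudobulk import ClusterCounts

    outdir = Path(outdir)
    data: dict[str, ClusterCounts] = {}
    metas = []
    for f in sorted(outdir.glob("pseudobulk_*.tsv")):
        cluster = f.stem.removeprefix("pseudobulk_")
        Y = pd.read_csv(f, sep="\t", index_col=0).T
        Y.index.name = "sample"
        Y.columns.name = "gene"
        samples = pd.read_csv(outdir / f"samples_{cluster}.tsv", sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        samples.index.name = "sample"
        Y.index = Y.index.astype(str)
        n = samples["n_cells"]
        data[cluster] = ClusterCounts(Y.astype(np.int64), n.rename("n_cells"))
        metas.append(samples.drop(columns=["n_cells"]))
    meta = pd.concat(metas).groupby(level=0).first() if metas else pd.DataFrame()
    return PseudobulkSet(data=data, sample_meta=meta)
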