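"""End-to-end differential expression pipeline over in-memory cell counts.

aggregate -> filter samples -> filter genes -> log2-CPM -> cell-count weights
-> mean-variance trend weights -> per-gene weighted LMM -> mixture-matched
residual df -> empirical-Bayes moderation -> study-wide BH.

This is the library core; the CLI/workflow module wraps it with config
handling and file IO, and the calibration harness drives it on simulated
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .moderation import adjust_fdr, moderate_cluster
from .pseudobulk import (
    CellCounts,
    LogExpression,
    PseudobulkSet,
    aggregate,
    filter_genes,
    filter_samples,
    log2cpm,
)
from .regression import ModelSpec, fit_cluster
from .weights import (
    cell_count_weights,
    combine_weights,
    fit_mean_variance_trend,
    trend_weights,
)

__all__ = ["PipelineResult", "run_de_pipeline", "de_from_pseudobulk"]


@dataclass
class PipelineResult:
    """Outputs of a full DE run: result table plus per-cluster intermediates."""

    table: pd.DataFrame
    pseudobulk: PseudobulkSet
    expressions: dict[str, LogExpression] = field(default_factory=dict)
    weights: dict[str, pd.DataFrame] = field(default_factory=dict)
    trends: dict[str, object] = field(default_factory=dict)
    diagnostics: dict[str, pd.DataFrame] = field(default_factory=dict)
    priors: dict[str, object] = field(default_factory=dict)


def de_from_pseudobulk(
    pb: PseudobulkSet,
    spec: ModelSpec,
    min_cells: int = 10,
    min_count: float = 5,
    min_prop: float = 0.3,
    use_trend_weights: bool = True,
    use_cell_weights: bool = True,
    fdr_scope: str = "study",
    workers: int = 1,
) -> PipelineResult:
    """Run filtering, weighting, per-gene fits and moderation on pseudobulk."""
    pb = filter_samples(pb, min_cells=min_cells)
    pb = filter_genes(pb, min_count=min_count, min_prop=min_prop)
    tables = []
    result = PipelineResult(table=pd.DataFrame(), pseudobulk=pb)
    for cluster, cc in pb.data.items():
        if cc.Y.shape[1] == 0:
            continue
        expr = log2cpm(cc)
        meta = pb.sample_meta.loc[expr.samples]
        cellw = (
            cell_count_weights(cc.n.to_numpy())
            if use_cell_weights
            else np.ones(len(expr.samples))
        )
        from .regression import build_design

        design0 = build_design(meta, spec)
        if use_trend_weights and expr.E.shape[1] >= 10:
            expr_fit = LogExpression(
                E=expr.E.loc[design0.rows], lib_size=expr.lib_size.loc[design0.rows]
            )
            trend = fit_mean_variance_trend(
                expr_fit, design0.X, init_weights=cellw[expr.samples.get_indexer(design0.rows)]
            )
            tW = trend_weights(trend, expr_fit)
            tW = tW.reindex(expr.samples).fillna(1.0)
            result.trends[cluster] = trend
        else:
            tW = pd.DataFrame(1.0, index=expr.samples, columns=expr.genes)
        W = combine_weights(cellw, tW)
        cfits = fit_cluster(expr, W, spec, meta, workers=workers)
        contrast = cfits.design.contrast_for(spec)
        tab = moderate_cluster(
            cfits, contrast, cluster, avg_expr=expr.E.mean(axis=0)
        )
        tables.append(tab)
        result.expressions[cluster] = expr
        result.weights[cluster] = W
        result.diagnostics[cluster] = cfits.diagnostics
        result.priors[cluster] = tab.attrs.get("prior")
    if tables:
        result.table = adjust_fdr(pd.concat(tables, ignore_index=True), scope=fdr_scope)
    return result


def run_de_pipeline(
    cells: CellCounts,
    sample_meta: pd.DataFrame,
    spec: ModelSpec,
    min_cells: int = 10,
    min_count: float = 5,
    min_prop: float = 0.3,
    block_size: int = 50_000,
    use_trend_weights: bool = True,
    use_cell_weights: bool = True,
    fdr_scope: str = "study",
    workers: int = 1,
) -> PipelineResult:
    """Aggregate cell counts and run the full DE pipeline.

    Deterministic given its inputs: no stochastic steps are involved in the
    DE path (only the simulator and the permutation harness take seeds).
    """
    pb = aggregate(cells, sample_meta=sample_meta, block_size=block_size)
    return de_from_pseudobulk(
        pb,
        spec,
        min_cells=min_cells,
        min_count=min_count,
        min_prop=min_prop,
        use_trend_weights=use_trend_weights,
        use_cell_weights=use_cell_weights,
        fdr_scope=fdr_scope,
        workers=workers,
    )
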