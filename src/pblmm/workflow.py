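"""Config-driven orchestration of the full workflow.

A single validated config drives aggregation, differential expression,
optional variance partitioning and gene set analysis; outputs are TSVs plus
a line-oriented log and a machine-readable JSON run summary. The DE path is
deterministic given config and input; only the simulator and the
permutation harness are seeded.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import io as pio
from .genesets import geneset_fdr, geneset_test, read_gmt
from .moderation import adjust_fdr
from .pipeline import de_from_pseudobulk
from .pseudobulk import aggregate
from .regression import ModelSpec
from .varpart import partition_variance

__all__ = ["RunConfig", "ConfigError", "DataError", "run_de"]


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 2)."""


class DataError(Exception):
    """Unreadable or inconsistent input data (CLI exit code 3)."""


class FormulaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fixed: list[str] = Field(default_factory=list)
    random: list[str] = Field(default_factory=list)
    coef: str | None = None
    contrast: list[float] | None = None
    reference: dict[str, str] = Field(default_factory=dict)


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_cells: int = 10
    min_count: float = 5
    min_prop: float = 0.3

    @field_validator("min_cells")
    @classmethod
    def _pos(cls, v: int) -> int:
        if v < 1:
            raise ValueError("min_cells must be >= 1")
        return v


class VarPartConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    random: list[str] = Field(default_factory=list)
    fixed: list[str] = Field(default_factory=list)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input: str
    dialect: str = "h5ad"  # "h5ad" or "mtx"
    cell_meta: str | None = None  # mtx dialect: cell metadata TSV
    genes: str | None = None  # mtx dialect: gene id TSV
    layer: str | None = None
    sample_col: str = "sample"
    cluster_col: str = "cluster"
    filters: FilterConfig = Field(default_factory=FilterConfig)
    formula: FormulaConfig = Field(default_factory=FormulaConfig)
    fdr_scope: str = "study"
    use_cell_weights: bool = True
    use_trend_weights: bool = True
    varpart: VarPartConfig | None = None
    geneset_file: str | None = None
    geneset_rho: float = 0.01
    outdir: str = "pblmm_out"
    seed: int = 0
    threads: int = 1

    @field_validator("dialect")
    @classmethod
    def _dialect(cls, v: str) -> str:
        if v not in ("h5ad", "mtx"):
            raise ValueError("dialect must be 'h5ad' or 'mtx'")
        return v

    @field_validator("fdr_scope")
    @classmethod
    def _scope(cls, v: str) -> str:
        if v not in ("study", "cluster"):
            raise ValueError("fdr_scope must be 'study' or 'cluster'")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            return cls.model_validate(raw or {})
        except Exception as exc:
            raise ConfigError(str(exc)) from exc


def _load_cells(cfg: RunConfig):
    try:
        if cfg.dialect == "h5ad":
            return pio.read_h5ad_cells(
                cfg.input, cfg.sample_col, cfg.cluster_col, layer=cfg.layer
            )
        if cfg.cell_meta is None or cfg.genes is None:
            raise ConfigError("mtx dialect requires cell_meta and genes paths")
        return pio.read_mtx_cells(
            cfg.input, cfg.cell_meta, cfg.genes, cfg.sample_col, cfg.cluster_col
        )
    except ConfigError:
        raise
    except (OSError, ValueError, KeyError) as exc:
        raise DataError(f"cannot load input {cfg.input}: {exc}") from exc


def run_de(cfg: RunConfig) -> Path:
    """Run the configured pipeline end to end; returns the output directory."""
    t_start = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}")

    spec = ModelSpec(
        fixed=list(cfg.formula.fixed),
        random=list(cfg.formula.random),
        coef=cfg.formula.coef,
        contrast=np.asarray(cfg.formula.contrast, float)
        if cfg.formula.contrast is not None
        else None,
        reference=dict(cfg.formula.reference),
    )
    if spec.coef is None and spec.contrast is None:
        raise ConfigError("formula must name a coef or a contrast")

    cells, sample_meta = _load_cells(cfg)
    missing = [
        t for t in list(spec.fixed) + list(spec.random) if t not in sample_meta.columns
    ]
    if missing:
        raise DataError(f"model terms missing from sample metadata: {missing}")
    log(f"loaded {cells.n_cells} cells x {cells.n_genes} genes from {cfg.input}")

    pb = aggregate(cells, sample_meta=sample_meta)
    result = de_from_pseudobulk(
        pb,
        spec,
        min_cells=cfg.filters.min_cells,
        min_count=cfg.filters.min_count,
        min_prop=cfg.filters.min_prop,
        use_trend_weights=cfg.use_trend_weights,
        use_cell_weights=cfg.use_cell_weights,
        fdr_scope=cfg.fdr_scope,
        workers=cfg.threads,
    )
    for line in result.pseudobulk.dropped:
        log(f"filter: {line}")

    table = result.table
    cols = ["cluster", "gene", "logFC", "AveExpr", "t", "P.Value", "adj.P.Val", "df"]
    if not table.empty:
        table[cols].to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        for cluster, sub in table.groupby("cluster"):
            sub[cols].to_csv(outdir / f"de_{cluster}.tsv", sep="\t", index=False)
    for cluster, diag in result.diagnostics.items():
        diag.to_csv(outdir / f"diagnostics_{cluster}.tsv", sep="\t", index=False)
    for cluster, trend in result.trends.items():
        pd.DataFrame({"mean_log2_count": trend.x, "sqrt_sd": trend.y}).to_csv(
            outdir / f"trend_{cluster}.tsv", sep="\t", index=False
        )
    log(f"differential expression: {len(table)} tests across {table['cluster'].nunique() if not table.empty else 0} clusters")

    if cfg.varpart is not None:
        vspec = ModelSpec(fixed=list(cfg.varpart.fixed), random=list(cfg.varpart.random), coef=None)
        vtabs = []
        for cluster, expr in result.expressions.items():
            vtabs.append(
                partition_variance(
                    expr, result.weights[cluster], vspec,
                    result.pseudobulk.sample_meta, cluster=cluster,
                )
            )
        if vtabs:
            pd.concat(vtabs, ignore_index=True).to_csv(
                outdir / "varpart.tsv", sep="\t", index=False
            )
            log("variance partitioning written")

    if cfg.geneset_file is not None and not table.empty:
        sets = read_gmt(cfg.geneset_file)
        gtabs = []
        for cluster, sub in table.groupby("cluster"):
            tstats = sub.set_index("gene")["t"]
            gtabs.append(geneset_test(tstats, sets, rho=cfg.geneset_rho, cluster=cluster))
        gres = geneset_fdr(pd.concat(gtabs, ignore_index=True))
        gres.to_csv(outdir / "genesets.tsv", sep="\t", index=False)
        log(f"gene set analysis: {len(gres)} cluster x set tests")

    import pblmm

    summary = {
        "version": pblmm.__version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_cells": int(cells.n_cells),
        "n_genes_input": int(cells.n_genes),
        "clusters": {
            c: {
                "n_samples": int(result.expressions[c].E.shape[0]),
                "n_genes": int(result.expressions[c].E.shape[1]),
            }
            for c in result.expressions
        },
        "n_tests": int(table["P.Value"].notna().sum()) if not table.empty else 0,
        "n_fdr05": int((table["adj.P.Val"] < 0.05).sum()) if not table.empty else 0,
        "dropped": result.pseudobulk.dropped,
        "elapsed_sec": round(time.time() - t_start, 2),
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log("run complete")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
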