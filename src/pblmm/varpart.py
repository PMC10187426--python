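"""Variance partitioning: per-gene decomposition of expression variance.

Each annotated source of variation contributes a variance component: every
categorical source is modeled as a random intercept (so it has an estimated
variance even for a two-level factor such as diagnosis), each continuous
source as a fixed effect whose contribution is the empirical variance of its
fitted term, plus the residual. Fractions are the components divided by
their total, so they are non-negative and sum to one per gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pseudobulk import LogExpression
from .regression import ModelSpec, build_design, fit_gene

__all__ = ["partition_variance", "summarize_varpart"]


def partition_variance(
    expr: LogExpression,
    W: pd.DataFrame | None,
    spec: ModelSpec,
    sample_meta: pd.DataFrame,
    cluster: str = "cluster",
) -> pd.DataFrame:
    """Fit the weighted LMM per gene and return per-source variance fractions.

    ``spec.random`` lists the categorical sources (each needs >= 2 levels),
    ``spec.fixed`` the continuous ones (each non-constant). The observation
    weights ``W`` are the same ones used for differential expression (ones if
    None). Non-converged genes are flagged and excluded from summaries.
    """
    design = build_design(sample_meta.loc[expr.samples], spec)
    for t in spec.fixed:
        col = sample_meta.loc[design.rows, t]
        if not pd.api.types.is_numeric_dtype(col):
            raise ValueError(
                f"fixed source {t!r} must be continuous; model categorical sources as random"
            )
        if col.nunique() < 2:
            raise ValueError(f"continuous source {t!r} is constant")
    rows = design.rows
    E = expr.E.loc[rows].to_numpy(dtype=float)
    if W is None:
        Wa = np.ones_like(E)
    else:
        Wa = W.loc[rows, expr.genes].to_numpy(dtype=float)

    comp_names = list(spec.random) + list(spec.fixed) + ["Residuals"]
    fixed_cols: dict[str, list[int]] = {
        t: [j for j, c in enumerate(design.columns) if c == t] for t in spec.fixed
    }

    records = []
    for j, gene in enumerate(expr.genes):
        fit = fit_gene(E[:, j], Wa[:, j], design.X, design.Zs, design.columns)
        row: dict[str, object] = {"cluster": cluster, "gene": str(gene)}
        if not fit.converged:
            row.update({c: np.nan for c in comp_names})
            row["converged"] = False
            records.append(row)
            continue
        parts: dict[str, float] = {}
        for t in spec.random:
            parts[t] = max(fit.varcomp.get(t, 0.0), 0.0)
        for t in spec.fixed:
            idx = fixed_cols[t]
            contrib = design.X[:, idx] @ fit.beta[idx]
            parts[t] = float(np.var(contrib, ddof=1))
        parts["Residuals"] = max(fit.sigma2_reml, 0.0)
        total = sum(parts.values())
        if total <= 0:
            row.update({c: np.nan for c in comp_names})
            row["converged"] = False
        else:
            row.update({c: v / total for c, v in parts.items()})
            row["converged"] = True
        records.append(row)
    return pd.DataFrame.from_records(records)


def summarize_varpart(
    tab: pd.DataFrame, thresholds: tuple[float, ...] = (0.05, 0.25)
) -> pd.DataFrame:
    """Per-component medians, quartiles and threshold-exceedance fractions.

    Exceedance at threshold tau counts genes with fraction strictly greater
    than tau (so threshold 0 counts genes with any positive fraction).
    """
    if tab.empty:
        raise ValueError("empty variance-partition table")
    use = tab[tab.get("converged", True) == True]  # noqa: E712
    comps = [
        c
        for c in tab.columns
        if c not in ("cluster", "gene", "converged")
    ]
    rows = []
    for c in comps:
        vals = use[c].astype(float).dropna()
        row = {
            "component": c,
            "median": vals.median(),
            "q25": vals.quantile(0.25),
            "q75": vals.quantile(0.75),
        }
        for tau in thresholds:
            row[f"frac_gt_{tau}"] = float((vals > tau).mean())
        rows.append(row)
    return pd.DataFrame(rows)
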