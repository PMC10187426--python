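"""Figure generation from the TSV outputs of a completed run.

Every plot is a pure function of the tables on disk: mean-variance trend
scatter per cluster, volcano per cluster, variance-fraction violins, and a
clusters x sets heatmap of gene set z-scores. Each plot also exports its
plotted data as CSV so figures are testable without image comparison.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_outputs"]


def _volcano(de: pd.DataFrame, cluster: str, outdir: Path) -> None:
    sub = de[de["cluster"] == cluster].dropna(subset=["logFC", "P.Value"])
    if sub.empty:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = sub["adj.P.Val"] < 0.05
    ax.scatter(sub["logFC"], -np.log10(sub["P.Value"]), s=6,
               c=np.where(sig, "crimson", "grey"), alpha=0.6, linewidths=0)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{cluster}: differential expression")
    fig.tight_layout()
    fig.savefig(outdir / f"volcano_{cluster}.png", dpi=120)
    plt.close(fig)
    sub[["gene", "logFC", "P.Value", "adj.P.Val"]].to_csv(
        outdir / f"volcano_{cluster}.csv", index=False
    )


def _trend(trend: pd.DataFrame, cluster: str, outdir: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(trend["mean_log2_count"], trend["sqrt_sd"], color="steelblue")
    ax.set_xlabel("average log2 count")
    ax.set_ylabel("sqrt(residual sd)")
    ax.set_title(f"{cluster}: mean-variance trend")
    fig.tight_layout()
    fig.savefig(outdir / f"trend_{cluster}.png", dpi=120)
    plt.close(fig)


def _violin(vp: pd.DataFrame, outdir: Path) -> None:
    comps = [c for c in vp.columns if c not in ("cluster", "gene", "converged")]
    for cluster, sub in vp.groupby("cluster"):
        use = sub[sub.get("converged", True) == True]  # noqa: E712
        data = [use[c].dropna().to_numpy() for c in comps]
        if not any(len(d) for d in data):
            continue
        fig, ax = plt.subplots(figsize=(1 + len(comps), 4))
        ax.violinplot([d for d in data if len(d)], showmedians=True)
        ax.set_xticks(range(1, len(comps) + 1), comps, rotation=45, ha="right")
        ax.set_ylabel("fraction of variance")
        ax.set_title(f"{cluster}: variance partitioning")
        fig.tight_layout()
        fig.savefig(outdir / f"varpart_{cluster}.png", dpi=120)
        plt.close(fig)
        long = use.melt(
            id_vars=["cluster", "gene"], value_vars=comps,
            var_name="component", value_name="fraction",
        )
        long.to_csv(outdir / f"varpart_{cluster}.csv", index=False)


def _geneset_heatmap(gs: pd.DataFrame, outdir: Path) -> None:
    wide = gs.pivot_table(index="set", columns="cluster", values="z")
    if wide.empty:
        return
    fig, ax = plt.subplots(figsize=(2 + wide.shape[1], 1 + 0.3 * wide.shape[0]))
    vmax = np.nanmax(np.abs(wide.to_numpy())) or 1.0
    im = ax.imshow(wide.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(wide.shape[0]), wide.index)
    fig.colorbar(im, ax=ax, label="z")
    fig.tight_layout()
    fig.savefig(outdir / "genesets_heatmap.png", dpi=120)
    plt.close(fig)
    wide.to_csv(outdir / "genesets_heatmap.csv")


def plot_outputs(outdir) -> list[str]:
    """Generate all figures available from a run directory; returns warnings
    for tables that were missing (the corresponding plots are skipped)."""
    outdir = Path(outdir)
    warnings: list[str] = []
    de_path = outdir / "de_results.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t")
        if de.empty:
            warnings.append("de_results.tsv is empty; volcano plots skipped")
        else:
            for cluster in de["cluster"].unique():
                _volcano(de, str(cluster), outdir)
    else:
        warnings.append("de_results.tsv missing; volcano plots skipped")
    trends = sorted(outdir.glob("trend_*.tsv"))
    if trends:
        for f in trends:
            _trend(pd.read_csv(f, sep="\t"), f.stem.removeprefix("trend_"), outdir)
    else:
        warnings.append("no trend tables; mean-variance plots skipped")
    vp_path = outdir / "varpart.tsv"
    if vp_path.exists():
        _violin(pd.read_csv(vp_path, sep="\t"), outdir)
    else:
        warnings.append("varpart.tsv missing; violin plots skipped")
    gs_path = outdir / "genesets.tsv"
    if gs_path.exists():
        _geneset_heatmap(pd.read_csv(gs_path, sep="\t"), outdir)
    else:
        warnings.append("genesets.tsv missing; heatmap skipped")
    return warnings
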