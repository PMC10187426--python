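"""Synthetic single-cell data with subject, batch and disease structure.

Cell-level counts are negative-binomial: for gene g in a cell of sample
(subject i, replicate r),

    count ~ NB(mean = depth_per_cell * p_{i,r,g}, dispersion theta)
    p_{i,r,g} = exp(eta_{i,r,g}) / sum_g exp(eta_{i,r,g})
    eta_{i,r,g} = m_g + ln(2) * (a_i + b_{batch(i)} + x_i * beta_g)

with gene baseline m_g drawn once per dataset, subject effects
a_i ~ N(0, sigma2_subject) and batch effects b ~ N(0, sigma2_batch) on the
log2 scale (hence the ln 2 factor), and beta_g = +/- lfc_de (log2) for a
random frac_de subset of genes, zero otherwise. Replicates of a subject
share a_i and the subject's batch; each replicate is a distinct sample.

The module also provides the within-batch label permutation used for
false-positive-rate calibration (the case/control multiset of each batch is
preserved exactly) and a harness that scores FPR, observed FDR and power of
the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pipeline import run_de_pipeline
from .pseudobulk import CellCounts
from .regression import ModelSpec

__all__ = [
    "SimConfig",
    "simulate_dataset",
    "permute_within_batch",
    "CalibrationReport",
    "run_calibration",
]


@dataclass
class SimConfig:
    """Simulation settings.

    Variances ``sigma2_subject``/``sigma2_batch`` are on the log2-expression
    scale; ``lfc_de`` is a log2 fold change; ``dispersion`` is the
    negative-binomial size parameter (variance = mu + mu^2/dispersion);
    ``depth_per_cell`` is the mean total reads per cell. ``n_cells_per_subject``
    may be an int or an inclusive (low, high) range sampled per sample.
    ``frac_cases * n_subjects`` is rounded to the nearest integer.
    """

    n_subjects: int = 40
    n_cells_per_subject: int | tuple[int, int] = 100
    n_genes: int = 2000
    subjects_per_batch: int = 5
    frac_cases: float = 0.5
    frac_de: float = 0.0
    lfc_de: float = 1.0
    sigma2_subject: float = 0.05
    sigma2_batch: float = 0.05
    base_expr_mean: float = 0.0
    base_expr_sd: float = 1.5
    dispersion: float = 3.0
    depth_per_cell: float = 2000.0
    n_replicates_per_subject: int = 1
    seed: int = 0

    @property
    def n_batches(self) -> int:
        if self.n_subjects % self.subjects_per_batch != 0:
            raise ValueError(
                f"subjects_per_batch={self.subjects_per_batch} does not divide "
                f"n_subjects={self.n_subjects}"
            )
        return self.n_subjects // self.subjects_per_batch


def simulate_dataset(cfg: SimConfig) -> tuple[CellCounts, pd.DataFrame]:
    """Generate cell-level counts and sample metadata; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n_batches = cfg.n_batches
    G = cfg.n_genes

    subjects = [f"s{i:03d}" for i in range(cfg.n_subjects)]
    batch_of = {s: f"b{i // cfg.subjects_per_batch:02d}" for i, s in enumerate(subjects)}
    # round-robin within batch keeps case/control near-balanced per batch
    n_cases = int(round(cfg.frac_cases * cfg.n_subjects))
    order = np.argsort([i % cfg.subjects_per_batch for i in range(cfg.n_subjects)], kind="stable")
    status = np.zeros(cfg.n_subjects, dtype=int)
    status[order[:n_cases]] = 1
    dx = {s: ("case" if status[i] else "control") for i, s in enumerate(subjects)}

    m = rng.normal(cfg.base_expr_mean, cfg.base_expr_sd, size=G)
    # random effects are gene-specific: a gene-shared (scalar) shift would be
    # absorbed by library-size normalization and carry no expression signal
    a = rng.normal(0.0, np.sqrt(cfg.sigma2_subject), size=(cfg.n_subjects, G))
    b = rng.normal(0.0, np.sqrt(cfg.sigma2_batch), size=(n_batches, G))
    beta = np.zeros(G)
    n_de = int(round(cfg.frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    if n_de:
        beta[de_idx] = cfg.lfc_de * rng.choice([-1.0, 1.0], size=n_de)

    ln2 = np.log(2.0)
    blocks = []
    cell_sample: list[str] = []
    meta_rows = []
    for i, s in enumerate(subjects):
        bi = int(batch_of[s][1:])
        for r in range(cfg.n_replicates_per_subject):
            sid = s if cfg.n_replicates_per_subject == 1 else f"{s}r{r}"
            eta = m + ln2 * (a[i] + b[bi] + status[i] * beta)  # all length-G vectors
            p = np.exp(eta - eta.max())
            p /= p.sum()
            if isinstance(cfg.n_cells_per_subject, tuple):
                lo, hi = cfg.n_cells_per_subject
                ncells = int(rng.integers(lo, hi + 1))
            else:
                ncells = int(cfg.n_cells_per_subject)
            mu = cfg.depth_per_cell * p  # shared across cells of this sample
            lam = rng.gamma(cfg.dispersion, scale=mu / cfg.dispersion, size=(ncells, G))
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts))
            cell_sample.extend([sid] * ncells)
            meta_rows.append(
                {
                    "sample": sid,
                    "subject": s,
                    "batch": batch_of[s],
                    "diagnosis": dx[s],
                    "replicate": r,
                }
            )
    counts = sp.vstack(blocks).tocsr()
    gene_ids = np.array([f"g{j:05d}" for j in range(G)], dtype=object)
    cells = CellCounts(
        counts=counts,
        cell_sample=np.array(cell_sample, dtype=object),
        cell_cluster=np.array(["c0"] * counts.shape[0], dtype=object),
        gene_ids=gene_ids,
    )
    sample_meta = pd.DataFrame(meta_rows).set_index("sample")
    sample_meta.attrs["de_genes"] = [f"g{j:05d}" for j in sorted(de_idx)]
    sample_meta.attrs["lfc"] = {f"g{j:05d}": float(beta[j]) for j in de_idx}
    return cells, sample_meta


def permute_within_batch(labels: pd.Series, batch: pd.Series, seed: int) -> pd.Series:
    """Permute labels uniformly at random within each batch.

    The multiset of labels in every batch is preserved exactly, so the
    case/control fraction per batch is unchanged; only the assignment to
    subjects is randomized. Seed-reproducible.
    """
    if not labels.index.equals(batch.index):
        raise ValueError("labels and batch must share an index")
    rng = np.random.default_rng(seed)
    out = labels.copy()
    for _, idx in batch.groupby(batch).groups.items():
        vals = labels.loc[idx].to_numpy()
        out.loc[idx] = rng.permutation(vals)
    return out


@dataclass
class CalibrationReport:
    """Aggregated calibration metrics per model variant."""

    fpr: pd.DataFrame  # variant, alpha, fpr, mc_se, n_reps
    fdr: pd.DataFrame  # variant, nominal, observed_fdr, power, mc_se, n_reps
    per_replicate: pd.DataFrame = field(default_factory=pd.DataFrame)


def _null_pvalues(table: pd.DataFrame, de_genes: set[str]) -> np.ndarray:
    null = table[~table["gene"].isin(de_genes)]
    return null["P.Value"].dropna().to_numpy()


def run_calibration(
    cfg: SimConfig,
    variants: dict[str, ModelSpec],
    n_reps: int = 20,
    alphas: tuple[float, ...] = (0.01, 0.05, 0.10),
    nominal_fdrs: tuple[float, ...] = (0.05, 0.10),
    min_cells: int = 10,
    min_count: float = 5,
    min_prop: float = 0.3,
) -> CalibrationReport:
    """Score FPR (null config) or FDR/power (frac_de > 0) of the full pipeline.

    With ``cfg.frac_de == 0`` one dataset is simulated and the diagnosis
    labels are permuted within batch for each replicate (the permutation
    design of the false-positive-rate experiment); otherwise each replicate
    simulates an independent dataset and BH discoveries are scored against
    the known DE genes.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fpr_rows, fdr_rows, per_rep = [], [], []
    if cfg.frac_de == 0:
        cells, sample_meta = simulate_dataset(cfg)
        subj_meta = sample_meta.drop_duplicates(subset=["subject"]).set_index("subject")
        for rep in range(n_reps):
            perm = permute_within_batch(
                subj_meta["diagnosis"], subj_meta["batch"], seed=cfg.seed + 1000 + rep
            )
            meta = sample_meta.copy()
            meta["diagnosis"] = perm.loc[meta["subject"]].to_numpy()
            for vname, spec in variants.items():
                res = run_de_pipeline(
                    cells, meta, spec,
                    min_cells=min_cells, min_count=min_count, min_prop=min_prop,
                )
                pvals = res.table["P.Value"].dropna().to_numpy()
                for alpha in alphas:
                    rate = float((pvals < alpha).mean()) if pvals.size else np.nan
                    per_rep.append(
                        {"variant": vname, "rep": rep, "alpha": alpha,
                         "fpr": rate, "n_tests": pvals.size}
                    )
        pr = pd.DataFrame(per_rep)
        for (vname, alpha), grp in pr.groupby(["variant", "alpha"]):
            rates = grp["fpr"].dropna()
            fpr_rows.append(
                {
                    "variant": vname, "alpha": alpha,
                    "fpr": float(rates.mean()),
                    "mc_se": float(rates.std(ddof=1) / np.sqrt(len(rates)))
                    if len(rates) > 1 else np.nan,
                    "n_reps": len(rates),
                }
            )
    else:
        for rep in range(n_reps):
            rep_cfg = replace(cfg, seed=cfg.seed + rep)
            cells, sample_meta = simulate_dataset(rep_cfg)
            de_genes = set(sample_meta.attrs["de_genes"])
            for vname, spec in variants.items():
                res = run_de_pipeline(
                    cells, sample_meta, spec,
                    min_cells=min_cells, min_count=min_count, min_prop=min_prop,
                )
                tab = res.table.dropna(subset=["P.Value"])
                pvals = _null_pvalues(tab, de_genes)
                for alpha in alphas:
                    per_rep.append(
                        {"variant": vname, "rep": rep, "alpha": alpha,
                         "fpr": float((pvals < alpha).mean()) if pvals.size else np.nan,
                         "n_tests": pvals.size}
                    )
                n_de_testable = int(tab["gene"].isin(de_genes).sum())
                for nominal in nominal_fdrs:
                    disc = tab[tab["adj.P.Val"] < nominal]
                    n_disc = len(disc)
                    n_false = int((~disc["gene"].isin(de_genes)).sum())
                    n_true = n_disc - n_false
                    fdr_rows.append(
                        {
                            "variant": vname, "rep": rep, "nominal": nominal,
                            "observed_fdr": n_false / n_disc if n_disc else 0.0,
                            "power": n_true / n_de_testable if n_de_testable else np.nan,
                            "n_discoveries": n_disc,
                        }
                    )
        pr = pd.DataFrame(per_rep)
        for (vname, alpha), grp in pr.groupby(["variant", "alpha"]):
            rates = grp["fpr"].dropna()
            fpr_rows.append(
                {
                    "variant": vname, "alpha": alpha, "fpr": float(rates.mean()),
                    "mc_se": float(rates.std(ddof=1) / np.sqrt(len(rates)))
                    if len(rates) > 1 else np.nan,
                    "n_reps": len(rates),
                }
            )
    fdr_df = pd.DataFrame(fdr_rows)
    fdr_agg = pd.DataFrame()
    if not fdr_df.empty:
        rows = []
        for (vname, nominal), grp in fdr_df.groupby(["variant", "nominal"]):
            obs = grp["observed_fdr"]
            rows.append(
                {
                    "variant": vname, "nominal": nominal,
                    "observed_fdr": float(obs.mean()),
                    "mc_se": float(obs.std(ddof=1) / np.sqrt(len(obs)))
                    if len(obs) > 1 else np.nan,
                    "power": float(grp["power"].mean()),
                    "n_reps": len(grp),
                }
            )
        fdr_agg = pd.DataFrame(rows)
    rep_frames = [pd.DataFrame(per_rep)]
    if not fdr_df.empty:
        rep_frames.append(fdr_df)
    return CalibrationReport(
        fpr=pd.DataFrame(fpr_rows),
        fdr=fdr_agg,
        per_replicate=pd.concat(rep_frames, ignore_index=True, sort=False),
    )
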