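"""Empirical-Bayes moderation for precision-weighted linear mixed models.

The residual variance of a weighted LMM is the quadratic form

    s^2 = y' P W^{-1} P y / df_r,   P = V0^{-1} - V0^{-1} X (X'V0^{-1}X)^{-1} X'V0^{-1},

with V0 the marginal covariance in relative-variance parameterization
(V0 = diag(1/w) + sum_k gamma_k Z_k Z_k'). Under the model the numerator is
distributed as a weighted mixture of chi-square(1) variables with weights
lambda_i equal to the eigenvalues of V0^{1/2} P W^{-1} P V0^{1/2} (times the
true residual variance). Matching the mean of that mixture with a single
chi-square gives the effective residual degrees of freedom

    df_r = sum_i lambda_i = tr(P W^{-1} P V0),

which is exact (df_r = n - p) for a pure weighted linear model and
approximate otherwise, improving with sample size.

Given per-gene (s^2, df_r), the prior (d0, s0^2) of a scaled inverse
chi-square is estimated by matching moments of log s^2 against the log-F
distribution (digamma/trigamma equations), the posterior variance is the
d0/df-weighted convex combination of s0^2 and s^2, and the moderated t uses
a Student-t null with d0 + df_r degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .regression import ClusterFits, GeneFit, finalize_fit_scale, test_contrast

__all__ = [
    "ResidualDfInfo",
    "EBPrior",
    "residual_df",
    "estimate_prior",
    "moderate",
    "moderate_cluster",
    "adjust_fdr",
]


@dataclass
class ResidualDfInfo:
    """Mixture weights (diagnostic, optional) and the mean-matched residual df."""

    lambdas: np.ndarray | None
    df_resid: float


def residual_df(
    fit: GeneFit,
    X: np.ndarray,
    Zs: dict[str, np.ndarray] | None,
    w: np.ndarray,
    full_spectrum: bool = False,
) -> ResidualDfInfo:
    """Residual degrees of freedom of a weighted LMM by chi-square-mixture mean matching.

    For a pure linear model this returns exactly n - p. For mixed models the
    trace tr(P W^{-1} P V0) is computed at the plug-in REML estimates; the
    full eigenvalue spectrum (the mixture weights) is computed only when
    ``full_spectrum`` is requested, since mean matching needs only the sum.
    """
    if not fit.converged:
        raise ValueError("cannot compute residual df for a non-converged fit")
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = X.shape
    Zs = Zs or {}
    if not Zs or all(fit.gamma.get(k, 0.0) == 0.0 for k in Zs):
        lam = None
        if full_spectrum:
            lam = np.concatenate([np.ones(n - p), np.zeros(p)])
        return ResidualDfInfo(lambdas=lam, df_resid=float(n - p))

    V0 = np.diag(1.0 / w)
    for name, Z in Zs.items():
        V0 += fit.gamma.get(name, 0.0) * (np.asarray(Z, float) @ np.asarray(Z, float).T)
    c = sla.cho_factor(V0, lower=True)
    ViX = sla.cho_solve(c, X)
    XtViX_inv = sla.cho_solve(sla.cho_factor(X.T @ ViX, lower=True), np.eye(p))
    P = sla.cho_solve(c, np.eye(n)) - ViX @ XtViX_inv @ ViX.T
    M = P @ np.diag(1.0 / w) @ P  # quadratic-form matrix of the residual variance
    if full_spectrum:
        # eigenvalues of V0^{1/2} M V0^{1/2}: symmetric PSD, sum = df
        Lchol = np.linalg.cholesky(V0)
        lam = np.linalg.eigvalsh(Lchol.T @ M @ Lchol)
        lam = np.clip(lam, 0.0, None)
        df = float(lam.sum())
        return ResidualDfInfo(lambdas=lam[::-1], df_resid=df)
    df = float(np.trace(M @ V0))
    return ResidualDfInfo(lambdas=None, df_resid=df)


@dataclass
class EBPrior:
    """Scaled-inverse-chi-square prior on residual variances: df d0, scale s0^2."""

    d0: float  # may be inf when gene variances are homogeneous
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2, df) -> EBPrior:
    """Estimate (d0, s0^2) by moment matching on log residual variances.

    With s^2 | sigma^2 ~ sigma^2 chi^2_df / df and sigma^2 ~ s0^2 d0 / chi^2_d0,
    e = log s^2 - digamma(df/2) + log(df/2) has mean log s0^2 + digamma(d0/2)
    - log(d0/2) and excess variance trigamma(d0/2) beyond the sampling term
    trigamma(df/2). When the excess is <= 0 the prior is degenerate (d0 = inf)
    and s0^2 is the common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        if s2.size == 1:
            return EBPrior(d0=np.inf, s0_sq=float(s2[0]))
        raise ValueError("need at least 2 genes with valid s^2 and df")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if evar <= 0:
        # no excess variance beyond sampling: degenerate prior at the mean
        return EBPrior(d0=np.inf, s0_sq=float(s2.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    if not np.isfinite(d0):
        return EBPrior(d0=np.inf, s0_sq=float(s2.mean()))
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBPrior(d0=d0, s0_sq=s0_sq)


def moderate(
    estimates: np.ndarray,
    ses: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray,
    prior: EBPrior,
):
    """Moderated t-statistics and two-sided p-values.

    Posterior variance s~^2 = (d0 s0^2 + df s^2) / (d0 + df); the moderated t
    rescales the raw t by s/s~ and is referred to a Student-t with d0 + df
    degrees of freedom (normal when d0 is infinite).
    """
    estimates = np.asarray(estimates, float)
    ses = np.asarray(ses, float)
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    t_mod = estimates / (ses * np.sqrt(s2_post / s2))
    p = np.where(
        np.isinf(df_total),
        2.0 * norm.sf(np.abs(t_mod)),
        2.0 * t_dist.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return t_mod, p, s2_post, df_total


def moderate_cluster(
    cfits: ClusterFits,
    contrast: np.ndarray,
    cluster: str,
    avg_expr: pd.Series | None = None,
    prior: EBPrior | None = None,
) -> pd.DataFrame:
    """Contrast, residual df and EB moderation for every converged gene of a cluster.

    Non-converged genes are excluded from the prior estimate and reported
    with NA statistics. Returns the per-cluster result table (no FDR; use
    :func:`adjust_fdr` across clusters for study-wide control).
    """
    X, Zs = cfits.design.X, cfits.design.Zs
    rows = cfits.design.rows
    n_genes = len(cfits.genes)
    est = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    s2 = np.full(n_genes, np.nan)
    dfr = np.full(n_genes, np.nan)
    for j, fit in enumerate(cfits.fits):
        if not fit.converged:
            continue
        w = getattr(fit, "_weights", None)
        if w is None:
            w = np.ones(fit.n_obs)
        info = residual_df(fit, X, Zs, w)
        finalize_fit_scale(fit, info.df_resid)
        try:
            est[j], se[j], _ = test_contrast(fit, contrast)
        except ValueError:
            continue
        s2[j] = fit.sigma2
        dfr[j] = info.df_resid
    ok = np.isfinite(est) & np.isfinite(se) & (se > 0) & np.isfinite(s2) & (s2 > 0)
    if prior is None:
        prior = estimate_prior(s2[ok], dfr[ok])
    t_mod = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    df_total = np.full(n_genes, np.nan)
    if ok.any():
        t_mod[ok], p[ok], _, df_total[ok] = moderate(
            est[ok], se[ok], s2[ok], dfr[ok], prior
        )
    out = pd.DataFrame(
        {
            "cluster": cluster,
            "gene": cfits.genes,
            "logFC": est,
            "AveExpr": (
                avg_expr.reindex(cfits.genes).to_numpy()
                if avg_expr is not None
                else np.nan
            ),
            "t": t_mod,
            "P.Value": p,
            "df": df_total,
            "s2": s2,
            "df_resid": dfr,
        }
    )
    out.attrs["prior"] = prior
    return out


def adjust_fdr(results: pd.DataFrame, scope: str = "study") -> pd.DataFrame:
    """Benjamini-Hochberg adjustment, once across all (cluster, gene) tests.

    ``scope='study'`` (default) applies BH to the concatenation across
    clusters; ``scope='cluster'`` adjusts within each cluster separately.
    """
    out = results.copy()
    out["adj.P.Val"] = np.nan
    if scope == "study":
        ok = out["P.Value"].notna()
        if ok.any():
            out.loc[ok, "adj.P.Val"] = multipletests(
                out.loc[ok, "P.Value"].to_numpy(), method="fdr_bh"
            )[1]
    elif scope == "cluster":
        for _, idx in out.groupby("cluster").groups.items():
            ok = out.loc[idx, "P.Value"].notna()
            sel = idx[ok]
            if len(sel):
                out.loc[sel, "adj.P.Val"] = multipletests(
                    out.loc[sel, "P.Value"].to_numpy(), method="fdr_bh"
                )[1]
    else:
        raise ValueError("scope must be 'study' or 'cluster'")
    return out
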