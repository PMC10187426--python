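"""Two-level precision weights for pseudobulk expression.

Level one: cell-count weights. The pseudobulk profile of a sample averages
over the cells observed for it, so the sampling variance of the underlying
expression state scales as 1/n_i and the relative precision is n_i — the
same for every gene within a sample.

Level two: mean-variance-trend weights. Counts on the log2-CPM scale are
heteroskedastic in a way that depends on expression magnitude; fitting a
weighted linear model per gene and smoothing sqrt(residual sd) against
average log2 count yields a trend whose inverse fourth power gives a
voom-style observation weight.

Only relative weights matter for the downstream weighted regression; the
combined matrix is normalized to mean one per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .pseudobulk import LogExpression

__all__ = [
    "cell_count_weights",
    "MeanVarTrend",
    "fit_mean_variance_trend",
    "trend_weights",
    "combine_weights",
]

# guard against degenerate trends; relative weights only, so clipping is safe
WEIGHT_FLOOR = 1e-6
WEIGHT_CEIL = 1e6


def cell_count_weights(n) -> np.ndarray:
    """Per-sample precision weights proportional to the number of cells observed.

    Normalized to mean one across samples; identical across genes.
    """
    n = np.asarray(n, dtype=float)
    if n.size == 0:
        raise ValueError("empty cell-count vector")
    if np.any(n <= 0) or not np.all(np.isfinite(n)):
        raise ValueError("cell counts must be positive and finite")
    return n / n.mean()


@dataclass
class MeanVarTrend:
    """Smoothed mean-variance trend: average log2 count -> sqrt residual sd.

    ``x``/``y`` are the lowess curve knots (x sorted); prediction uses linear
    interpolation with constant extrapolation beyond the fitted range.
    ``fitted_logcpm`` caches the per-observation fitted values of the gene-wise
    regressions so trend weights can be evaluated at fitted rather than
    observed abundances.
    """

    x: np.ndarray
    y: np.ndarray
    fitted_logcpm: pd.DataFrame | None = None

    def predict(self, x_new) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        return np.interp(x_new, self.x, self.y)


def _weighted_gene_fits(E: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Weighted least squares of every gene on a shared design and shared
    per-sample weights; returns (fitted, sigma) with sigma the residual sd."""
    n, p = X.shape
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    Ew = E * sw[:, None]
    beta, *_ = np.linalg.lstsq(Xw, Ew, rcond=None)
    fitted = X @ beta
    resid = E - fitted
    wrss = (w[:, None] * resid**2).sum(axis=0)
    sigma2 = wrss / (n - p)
    return fitted, np.sqrt(sigma2)


def fit_mean_variance_trend(
    expr: LogExpression,
    design: np.ndarray,
    init_weights: np.ndarray | None = None,
    span: float = 0.5,
    robust_iters: int = 1,
    min_genes: int = 10,
) -> MeanVarTrend:
    """Fit the lowess mean-variance trend from per-gene weighted linear fits.

    Each gene is regressed on ``design`` with per-sample ``init_weights``
    (cell-count weights; ones if omitted); the points
    (average log2 count, sqrt residual sd) are smoothed by locally weighted
    regression (span ``span``, ``robust_iters`` robustness iterations).
    """
    E = expr.E.to_numpy(dtype=float)
    n, G = E.shape
    X = np.asarray(design, dtype=float)
    if G < min_genes:
        raise ValueError(
            f"only {G} genes; need >= {min_genes} to fit a mean-variance trend "
            "(consider skipping trend weighting)"
        )
    p = X.shape[1]
    if n < p + 2:
        raise ValueError("need at least columns(design) + 2 samples")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full column rank")
    w = np.ones(n) if init_weights is None else np.asarray(init_weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("init_weights must be strictly positive")

    fitted, sigma = _weighted_gene_fits(E, X, w)
    ok = sigma > 1e-10  # exclude (numerically) constant genes
    if not ok.any():
        raise ValueError("all genes have zero residual sd; trend is undefined")

    lib = expr.lib_size.to_numpy(dtype=float)
    # average log2 count scale: shift log2-CPM back by the (log) library size
    shift = np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sx = E.mean(axis=0) + shift
    sy = np.sqrt(sigma)

    curve = lowess(sy[ok], sx[ok], frac=span, it=robust_iters, return_sorted=True)
    cx, cy = curve[:, 0], curve[:, 1]
    cx, first = np.unique(cx, return_index=True)
    cy = np.maximum(cy[first], 1e-6)

    fitted_df = pd.DataFrame(fitted, index=expr.E.index, columns=expr.E.columns)
    return MeanVarTrend(x=cx, y=cy, fitted_logcpm=fitted_df)


def trend_weights(
    trend: MeanVarTrend, expr: LogExpression, lib_size=None
) -> pd.DataFrame:
    """Observation weights from the mean-variance trend.

    Each observation's fitted log2 count is looked up on the trend curve and
    the weight is the predicted sqrt-sd to the power -4 (inverse variance of
    the log2-CPM value). Values beyond the fitted range use constant
    extrapolation of the nearest curve edge.
    """
    lib = expr.lib_size.to_numpy(dtype=float) if lib_size is None else np.asarray(lib_size, float)
    if trend.fitted_logcpm is not None and trend.fitted_logcpm.shape == expr.E.shape:
        base = trend.fitted_logcpm.to_numpy(dtype=float)
    else:
        base = expr.E.to_numpy(dtype=float)
    logcount = base + (np.log2(lib + 1.0) - np.log2(1e6))[:, None]
    sd_quarter = trend.predict(logcount)
    W = sd_quarter**-4.0
    W = np.clip(W, WEIGHT_FLOOR, WEIGHT_CEIL)
    return pd.DataFrame(W, index=expr.E.index, columns=expr.E.columns)


def combine_weights(cellw: np.ndarray, trendW: pd.DataFrame) -> pd.DataFrame:
    """Compose cell-count and trend weights multiplicatively.

    W[i, g] = cellw[i] * trendW[i, g], rescaled to mean one per gene.
    Downstream inference is invariant to per-gene rescaling.
    """
    cellw = np.asarray(cellw, dtype=float)
    if cellw.shape[0] != trendW.shape[0]:
        raise ValueError(
            f"cell weights ({cellw.shape[0]}) and trend weights "
            f"({trendW.shape[0]} samples) are misaligned"
        )
    W = trendW.to_numpy(dtype=float) * cellw[:, None]
    W = W / W.mean(axis=0, keepdims=True)
    return pd.DataFrame(W, index=trendW.index, columns=trendW.columns)
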