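"""Per-gene precision-weighted linear (mixed) models.

Each gene's log2-CPM vector y is modeled as

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e_i ~ N(0, s2_e / w_i)

with X the fixed-effect design, Z_k random-intercept indicators for grouping
factors (subject, batch/pool) and w_i the observation precision weights.
Variance components are estimated by restricted maximum likelihood with the
residual variance profiled out; fixed effects by generalized least squares at
the REML estimates. With no random terms the fit reduces exactly to weighted
least squares.

All matrices here are small (tens to hundreds of samples), so dense Cholesky
algebra per gene is both simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize, minimize_scalar

from .pseudobulk import LogExpression

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "GeneFit",
    "ClusterFits",
    "build_design",
    "fit_gene",
    "test_contrast",
    "fit_cluster",
]

# REML optimizer settings: log variance-ratio scale, bounded search
_LOG_GAMMA_LO = -12.0
_LOG_GAMMA_HI = 12.0
_REML_TOL = 1e-8
_REML_MAXITER = 200


@dataclass
class ModelSpec:
    """Model formula: ordered fixed terms, random-intercept terms, coefficient of interest.

    Categorical fixed terms are expanded to treatment-coded indicator columns
    with the reference level being the first in lexicographic order unless
    overridden via ``reference``. ``coef`` names one expanded fixed-effect
    column (e.g. ``"diagnosis[case]"``); alternatively ``contrast`` gives an
    explicit vector over the fixed-effect columns.
    """

    fixed: list[str] = field(default_factory=list)
    random: list[str] = field(default_factory=list)
    coef: str | None = None
    contrast: np.ndarray | None = None
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.fixed) & set(self.random)
        if overlap:
            raise ValueError(f"terms cannot be both fixed and random: {sorted(overlap)}")


@dataclass
class DesignInfo:
    """Expanded design: fixed matrix X with column names, random indicators Z_k."""

    X: np.ndarray
    columns: list[str]
    Zs: dict[str, np.ndarray]
    rows: pd.Index  # sample ids of retained rows
    dropped_rows: int = 0
    dropped_columns: list[str] = field(default_factory=list)

    def contrast_for(self, spec: ModelSpec) -> np.ndarray:
        if spec.contrast is not None:
            L = np.asarray(spec.contrast, dtype=float)
            if L.shape != (len(self.columns),):
                raise ValueError(
                    f"contrast length {L.shape} does not match {len(self.columns)} columns"
                )
            return L
        if spec.coef is None:
            raise ValueError("ModelSpec has neither coef nor contrast")
        matches = [j for j, c in enumerate(self.columns) if c == spec.coef]
        if not matches:
            # allow bare term name when it expands to a single column
            matches = [
                j
                for j, c in enumerate(self.columns)
                if c.split("[")[0] == spec.coef and c != "Intercept"
            ]
        if len(matches) != 1:
            raise ValueError(
                f"coef {spec.coef!r} resolves to {len(matches)} columns among {self.columns}"
            )
        L = np.zeros(len(self.columns))
        L[matches[0]] = 1.0
        return L


def build_design(sample_meta: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Expand a model spec against sample metadata into design matrices.

    Rows with missing values in any used column are dropped (count reported
    on the result). Aliased fixed-effect columns are removed by pivoted QR;
    if every column of a requested term is aliased the term is reported as an
    error. Random terms become indicator matrices over their levels.
    """
    used = list(spec.fixed) + list(spec.random)
    for t in used:
        if t not in sample_meta.columns:
            raise ValueError(f"term {t!r} not found in sample metadata")
    meta = sample_meta[used] if used else sample_meta.iloc[:, :0]
    keep = ~meta.isna().any(axis=1) if used else pd.Series(True, index=sample_meta.index)
    dropped_rows = int((~keep).sum())
    meta = sample_meta.loc[keep]

    cols: list[np.ndarray] = [np.ones(len(meta))]
    names: list[str] = ["Intercept"]
    term_of: dict[str, str] = {"Intercept": "Intercept"}
    for t in spec.fixed:
        col = meta[t]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            cols.append(col.to_numpy(dtype=float))
            names.append(t)
            term_of[t] = t
        else:
            levels = sorted(map(str, pd.unique(col.astype(str))))
            if len(levels) < 2:
                raise ValueError(
                    f"fixed term(s) fully aliased (constant or collinear): [{t!r}]"
                )
            ref = spec.reference.get(t, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not a level of {t!r}")
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{t}[{lev}]"
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(name)
                term_of[name] = t
    X = np.column_stack(cols)

    # drop aliased columns via pivoted QR, keeping the intercept first
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep_idx = sorted(piv[:rank])
    dropped_cols = [names[j] for j in range(X.shape[1]) if j not in keep_idx]
    if "Intercept" in dropped_cols:
        # pivoting may prefer an equivalent column; force intercept back in
        alt = [j for j in keep_idx if names[j] != "Intercept"]
        keep_idx = sorted([names.index("Intercept")] + alt[: rank - 1])
        dropped_cols = [names[j] for j in range(X.shape[1]) if j not in keep_idx]
    lost_terms = []
    for t in spec.fixed:
        t_cols = [c for c in names if term_of[c] == t]
        if t_cols and all(c in dropped_cols for c in t_cols):
            lost_terms.append(t)
    if lost_terms:
        raise ValueError(f"fixed term(s) fully aliased (constant or collinear): {lost_terms}")
    X = X[:, keep_idx]
    names = [names[j] for j in keep_idx]

    Zs: dict[str, np.ndarray] = {}
    for t in spec.random:
        col = meta[t].astype(str)
        levels = sorted(pd.unique(col))
        if len(levels) < 2:
            raise ValueError(f"random term {t!r} has a single level")
        Z = np.zeros((len(meta), len(levels)))
        for k, lev in enumerate(levels):
            Z[(col == lev).to_numpy(), k] = 1.0
        Zs[t] = Z

    return DesignInfo(
        X=X,
        columns=names,
        Zs=Zs,
        rows=meta.index,
        dropped_rows=dropped_rows,
        dropped_columns=dropped_cols,
    )


@dataclass
class GeneFit:
    """Result of one gene's weighted linear (mixed) model fit."""

    beta: np.ndarray
    se: np.ndarray
    sigma2: float  # residual variance estimate s^2 (EB input scale)
    varcomp: dict[str, float]  # random-effect variances s2_k
    df_resid: float | None  # filled by moderation.residual_df
    n_obs: int
    converged: bool
    columns: list[str] = field(default_factory=list)
    cov_unscaled: np.ndarray | None = None  # (X' V0^-1 X)^-1, relative scale
    gamma: dict[str, float] = field(default_factory=dict)  # s2_k / s2_reml
    sigma2_reml: float = np.nan  # profiled REML residual variance
    message: str = ""


def _v0_chol(w: np.ndarray, Zs: list[np.ndarray], gamma: np.ndarray):
    """Cholesky of V0 = diag(1/w) + sum_k gamma_k Z_k Z_k'."""
    V0 = np.diag(1.0 / w)
    for g, Z in zip(gamma, Zs):
        V0 += g * (Z @ Z.T)
    return V0, sla.cho_factor(V0, lower=True)


def _profiled_reml(log_gamma: np.ndarray, y, X, w, Zs):
    """-2 restricted log-likelihood with residual variance profiled out."""
    n, p = X.shape
    gamma = np.exp(log_gamma)
    V0, c = _v0_chol(w, Zs, gamma)
    ViX = sla.cho_solve(c, X)
    Viy = sla.cho_solve(c, y)
    XtViX = X.T @ ViX
    cx = sla.cho_factor(XtViX, lower=True)
    beta = sla.cho_solve(cx, X.T @ Viy)
    r = y - X @ beta
    q = float(r @ sla.cho_solve(c, r))
    q = max(q, 1e-300)
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(c[0])))
    logdet_XtViX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    return (n - p) * np.log(q / (n - p)) + logdet_V0 + logdet_XtViX


def fit_gene(
    y: np.ndarray,
    w: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray] | None = None,
    columns: list[str] | None = None,
) -> GeneFit:
    """Fit one gene by weighted least squares (no random terms) or REML.

    Deterministic: the REML optimizer is a bounded search on the log
    variance-ratio scale with fixed tolerances and no randomness. Variance
    components are constrained non-negative; boundary estimates are valid.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("length of y must match rows of X")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be strictly positive and finite")
    Zs = Zs or {}
    names = list(Zs.keys())
    Zlist = [np.asarray(Zs[k], dtype=float) for k in names]
    cols = columns if columns is not None else [f"x{j}" for j in range(p)]

    if not Zs:
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        XtWX = Xw.T @ Xw
        try:
            cx = sla.cho_factor(XtWX, lower=True)
        except sla.LinAlgError:
            return GeneFit(
                beta=np.full(p, np.nan), se=np.full(p, np.nan), sigma2=np.nan,
                varcomp={}, df_resid=None, n_obs=n, converged=False,
                columns=cols, message="singular weighted design",
            )
        beta = sla.cho_solve(cx, X.T @ (w * y))
        resid = y - X @ beta
        wrss = float(w @ resid**2)
        sigma2 = wrss / (n - p)
        cov_unscaled = sla.cho_solve(cx, np.eye(p))
        se = np.sqrt(np.maximum(sigma2 * np.diag(cov_unscaled), 0.0))
        fit = GeneFit(
            beta=beta, se=se, sigma2=sigma2, varcomp={}, df_resid=float(n - p),
            n_obs=n, converged=sigma2 > 0, columns=cols, cov_unscaled=cov_unscaled,
            gamma={}, sigma2_reml=sigma2,
            message="" if sigma2 > 0 else "zero residual variance",
        )
        fit._weights = w  # type: ignore[attr-defined]
        return fit

    K = len(Zlist)
    try:
        if K == 1:
            # One random term: whiten by sqrt(w) and rotate into the
            # eigenbasis of Z Z' so every REML evaluation is diagonal.
            sw = np.sqrt(w)
            d, U = np.linalg.eigh((Zlist[0] * sw[:, None]) @ (Zlist[0] * sw[:, None]).T)
            d = np.clip(d, 0.0, None)
            ys = U.T @ (sw * y)
            Xs = U.T @ (X * sw[:, None])

            def crit(lg: float) -> float:
                v = 1.0 + np.exp(lg) * d
                Xv = Xs / v[:, None]
                XtViX = Xs.T @ Xv
                cx = sla.cho_factor(XtViX, lower=True)
                beta = sla.cho_solve(cx, Xv.T @ ys)
                r = ys - Xs @ beta
                q = max(float(r @ (r / v)), 1e-300)
                return (
                    (n - p) * np.log(q / (n - p))
                    + float(np.log(v).sum())
                    + 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
                )

            res = minimize_scalar(
                crit,
                bounds=(_LOG_GAMMA_LO, _LOG_GAMMA_HI),
                method="bounded",
                options={"xatol": _REML_TOL, "maxiter": _REML_MAXITER},
            )
            log_gamma = np.array([res.x])
            ok = bool(res.success)
        else:
            res = minimize(
                _profiled_reml,
                x0=np.zeros(K),
                args=(y, X, w, Zlist),
                method="L-BFGS-B",
                bounds=[(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * K,
                options={"maxiter": _REML_MAXITER, "ftol": _REML_TOL, "gtol": 1e-7},
            )
            log_gamma = np.asarray(res.x)
            ok = bool(res.success)
    except (sla.LinAlgError, FloatingPointError) as exc:  # pragma: no cover
        return GeneFit(
            beta=np.full(p, np.nan), se=np.full(p, np.nan), sigma2=np.nan,
            varcomp={}, df_resid=None, n_obs=n, converged=False,
            columns=cols, message=f"REML failure: {exc}",
        )

    gamma = np.exp(log_gamma)
    # treat estimates at the lower bound as zero (boundary is a valid estimate)
    gamma[log_gamma <= _LOG_GAMMA_LO + 1e-6] = 0.0
    V0, c = _v0_chol(w, Zlist, gamma)
    ViX = sla.cho_solve(c, X)
    XtViX = X.T @ ViX
    cx = sla.cho_factor(XtViX, lower=True)
    beta = sla.cho_solve(cx, ViX.T @ y)
    r = y - X @ beta
    Vir = sla.cho_solve(c, r)
    sigma2_reml = float(r @ Vir) / (n - p)
    cov_unscaled = sla.cho_solve(cx, np.eye(p))

    # residual-variance quadratic form y' P W^-1 P y (P the REML projection);
    # its mean-matched scale is computed with the df in the moderation module,
    # here we store the numerator normalized by n - p as a provisional s^2 and
    # let residual_df() rescale (exactly equal for pure linear models).
    Pr = Vir  # P y = V0^-1 (y - X beta)
    s2_num = float(Pr @ ((1.0 / w) * Pr))
    varcomp = {name: float(g * sigma2_reml) for name, g in zip(names, gamma)}
    fit = GeneFit(
        beta=beta,
        se=np.full(p, np.nan),
        sigma2=np.nan,
        varcomp=varcomp,
        df_resid=None,
        n_obs=n,
        converged=ok and np.isfinite(sigma2_reml),
        columns=cols,
        cov_unscaled=cov_unscaled,
        gamma={name: float(g) for name, g in zip(names, gamma)},
        sigma2_reml=sigma2_reml,
    )
    fit._s2_numerator = s2_num  # type: ignore[attr-defined]
    fit._weights = w  # type: ignore[attr-defined]
    # df-dependent rescaling happens in moderation.residual_df; default to n-p
    fit.sigma2 = s2_num / (n - p)
    fit.se = np.sqrt(np.maximum(fit.sigma2 * np.diag(cov_unscaled), 0.0))
    return fit


def finalize_fit_scale(fit: GeneFit, df_resid: float) -> None:
    """Rescale s^2 and standard errors once the mixture-matched df is known."""
    num = getattr(fit, "_s2_numerator", None)
    if num is None:
        fit.df_resid = df_resid
        return
    fit.sigma2 = num / df_resid
    fit.se = np.sqrt(np.maximum(fit.sigma2 * np.diag(fit.cov_unscaled), 0.0))
    fit.df_resid = df_resid


def test_contrast(fit: GeneFit, contrast: np.ndarray):
    """Linear contrast on a fitted gene model: (estimate, se, raw_t).

    P-values are not computed here; the moderation module owns the null
    distribution.
    """
    L = np.asarray(contrast, dtype=float)
    if L.shape != fit.beta.shape:
        raise ValueError(f"contrast length {L.shape} != {fit.beta.shape}")
    if not np.any(L != 0):
        raise ValueError("null (all-zero) contrast")
    est = float(L @ fit.beta)
    var = float(L @ fit.cov_unscaled @ L) * fit.sigma2
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        raise ValueError("contrast has zero standard error (degenerate fit)")
    return est, se, est / se


@dataclass
class ClusterFits:
    """Per-gene fits for one cluster plus a diagnostics table."""

    genes: list[str]
    fits: list[GeneFit]
    design: DesignInfo
    diagnostics: pd.DataFrame

    def converged_mask(self) -> np.ndarray:
        return np.array([f.converged for f in self.fits], dtype=bool)


def fit_cluster(
    expr: LogExpression,
    W: pd.DataFrame,
    spec: ModelSpec,
    sample_meta: pd.DataFrame,
    workers: int = 1,
) -> ClusterFits:
    """Fit every gene in a cluster; per-gene failures are flagged, never fatal.

    Results are identical regardless of ``workers`` (fits are independent and
    deterministic; scheduling is reduction-order independent).
    """
    design = build_design(sample_meta.loc[expr.samples], spec)
    rows = design.rows
    E = expr.E.loc[rows]
    Wm = W.loc[rows]
    genes = [str(g) for g in E.columns]
    Ea = E.to_numpy(dtype=float)
    Wa = Wm.to_numpy(dtype=float)

    def _one(j: int) -> GeneFit:
        try:
            return fit_gene(Ea[:, j], Wa[:, j], design.X, design.Zs, design.columns)
        except ValueError as exc:
            p = design.X.shape[1]
            return GeneFit(
                beta=np.full(p, np.nan), se=np.full(p, np.nan), sigma2=np.nan,
                varcomp={}, df_resid=None, n_obs=len(rows), converged=False,
                columns=design.columns, message=str(exc),
            )

    if workers > 1:
        from joblib import Parallel, delayed

        fits = Parallel(n_jobs=workers, prefer="processes")(
            delayed(_one)(j) for j in range(len(genes))
        )
    else:
        fits = [_one(j) for j in range(len(genes))]

    diag = pd.DataFrame(
        {
            "gene": genes,
            "converged": [f.converged for f in fits],
            "sigma2": [f.sigma2 for f in fits],
            "message": [f.message for f in fits],
            **{
                f"varcomp_{t}": [f.varcomp.get(t, np.nan) for f in fits]
                for t in spec.random
            },
        }
    )
    return ClusterFits(genes=genes, fits=list(fits), design=design, diagnostics=diag)
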