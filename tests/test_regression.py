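import numpy as np
import pandas as pd
import pytest

from pblmm.pseudobulk import LogExpression
from pblmm.regression import ModelSpec, build_design, fit_cluster, fit_gene
from pblmm.regression import test_contrast as contrast_test


@pytest.fixture()
def meta6() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "diagnosis": ["case", "case", "control", "control", "case", "control"],
            "batch": ["b1", "b1", "b1", "b2", "b2", "b2"],
            "sex": ["M", "M", "M", "M", "M", "M"],
            "age": [70.0, 75.0, 80.0, 65.0, 72.0, 78.0],
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample"),
    )


class TestBuildDesign:
    def test_two_level_factor_gives_intercept_plus_indicator(self, meta6):
        info = build_design(meta6, ModelSpec(fixed=["diagnosis"]))
        assert info.X.shape == (6, 2)
        assert info.columns == ["Intercept", "diagnosis[control]"]
        np.testing.assert_array_equal(
            info.X[:, 1], (meta6["diagnosis"] == "control").astype(float)
        )

    def test_random_term_indicator(self, meta6):
        info = build_design(meta6, ModelSpec(fixed=["diagnosis"], random=["batch"]))
        Z = info.Zs["batch"]
        assert Z.shape == (6, 2)
        np.testing.assert_array_equal(Z.sum(axis=1), np.ones(6))
        np.testing.assert_array_equal(Z[:, 0], (meta6["batch"] == "b1").astype(float))

    def test_constant_factor_is_reported_as_aliased(self, meta6):
        with pytest.raises(ValueError, match="sex"):
            build_design(meta6, ModelSpec(fixed=["sex"]))

    def test_single_level_random_term_errors(self, meta6):
        with pytest.raises(ValueError, match="single level"):
            build_design(meta6, ModelSpec(random=["sex"]))

    def test_missing_rows_dropped_with_count(self, meta6):
        meta = meta6.copy()
        meta.loc["s2", "age"] = np.nan
        info = build_design(meta, ModelSpec(fixed=["diagnosis", "age"]))
        assert info.dropped_rows == 1
        assert "s2" not in info.rows

    def test_reference_level_override(self, meta6):
        info = build_design(
            meta6, ModelSpec(fixed=["diagnosis"], reference={"diagnosis": "control"})
        )
        assert info.columns == ["Intercept", "diagnosis[case]"]


class TestFitGene:
    def test_unweighted_fit_matches_ols_oracle(self):
        rng = np.random.default_rng(0)
        n = 15
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        fit = fit_gene(y, np.ones(n), X)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        np.testing.assert_allclose(fit.se, se, atol=1e-10)
        np.testing.assert_allclose(fit.sigma2, s2, atol=1e-10)

    def test_wls_equals_lmm_with_no_random_terms(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(8, 20))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.normal(size=n)
            w = rng.uniform(0.3, 3, size=n)
            f1 = fit_gene(y, w, X)
            f2 = fit_gene(y, w, X, {})
            np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-12)
            np.testing.assert_allclose(f1.sigma2, f2.sigma2, atol=1e-12)

    def test_zero_subject_variance_recovers_weighted_ols(self):
        rng = np.random.default_rng(2)
        n = 16
        subj = np.repeat(np.arange(8), 2)
        Z = np.zeros((n, 8))
        Z[np.arange(n), subj] = 1.0
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        w = rng.uniform(0.5, 2, size=n)
        # antisymmetric noise within subjects: within-subject correlation <= 0,
        # so the non-negative REML variance estimate hits the boundary at zero
        e = rng.normal(0, 0.5, 8)
        y = X @ [1.0, 0.5] + np.column_stack([e, -e]).ravel()
        flmm = fit_gene(y, w, X, {"subject": Z})
        fwls = fit_gene(y, w, X)
        assert flmm.varcomp["subject"] < 1e-4
        np.testing.assert_allclose(flmm.beta, fwls.beta, atol=1e-6)

    def test_reml_matches_statsmodels_mixedlm(self):
        """Independent oracle: unweighted random-intercept REML via statsmodels."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        n_subj, reps = 8, 3
        subj = np.repeat(np.arange(n_subj), reps)
        n = n_subj * reps
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.8, n_subj)[subj] + rng.normal(0, 0.5, n)
        X = np.column_stack([np.ones(n), x])
        Z = np.zeros((n, n_subj))
        Z[np.arange(n), subj] = 1.0
        fit = fit_gene(y, np.ones(n), X, {"subject": Z})
        m = smf.mixedlm(
            "y~x", pd.DataFrame({"y": y, "x": x, "subj": subj}), groups="subj"
        ).fit(reml=True)
        np.testing.assert_allclose(fit.beta, m.params[["Intercept", "x"]], atol=1e-5)
        np.testing.assert_allclose(fit.sigma2_reml, m.scale, rtol=1e-4)
        np.testing.assert_allclose(fit.varcomp["subject"], m.cov_re.iloc[0, 0], rtol=1e-3)

    def test_subject_random_effect_inflates_se_over_naive_fit(self):
        rng = np.random.default_rng(4)
        n_subj, reps = 10, 2
        subj = np.repeat(np.arange(n_subj), reps)
        n = n_subj * reps
        dx = np.repeat(rng.permutation(np.repeat([0.0, 1.0], n_subj // 2)), reps)
        X = np.column_stack([np.ones(n), dx])
        y = rng.normal(0, 2.0, n_subj)[subj] + rng.normal(0, 0.3, n)
        Z = np.zeros((n, n_subj))
        Z[np.arange(n), subj] = 1.0
        f_lmm = fit_gene(y, np.ones(n), X, {"subject": Z})
        f_naive = fit_gene(y, np.ones(n), X)
        assert f_lmm.se[1] > f_naive.se[1]

    def test_variance_components_location_invariant(self):
        rng = np.random.default_rng(5)
        n = 12
        subj = np.repeat(np.arange(6), 2)
        Z = np.zeros((n, 6))
        Z[np.arange(n), subj] = 1.0
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(0, 1, 6)[subj] + rng.normal(size=n)
        f1 = fit_gene(y, np.ones(n), X, {"s": Z})
        f2 = fit_gene(y + 1000.0, np.ones(n), X, {"s": Z})
        np.testing.assert_allclose(f1.varcomp["s"], f2.varcomp["s"], rtol=1e-4, atol=1e-8)
        np.testing.assert_allclose(f1.sigma2_reml, f2.sigma2_reml, rtol=1e-4)

    def test_nonpositive_weights_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="weights"):
            fit_gene(np.zeros(4), np.array([1.0, 0.0, 1.0, 1.0]), X)


class TestContrast:
    def test_single_coefficient_contrast(self):
        rng = np.random.default_rng(6)
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = fit_gene(rng.normal(size=n), np.ones(n), X)
        est, se, t = contrast_test(fit, np.array([0.0, 1.0]))
        assert est == pytest.approx(fit.beta[1])
        assert se == pytest.approx(fit.se[1])

    def test_null_contrast_rejected(self):
        fit = fit_gene(np.arange(5.0), np.ones(5), np.column_stack([np.ones(5), np.arange(5.0)]))
        with pytest.raises(ValueError, match="contrast"):
            contrast_test(fit, np.zeros(2))

    def test_level_difference_matches_releveled_refit(self):
        """Contrast between two non-reference levels equals refitting with the
        reference level changed (reparameterization oracle)."""
        rng = np.random.default_rng(7)
        grp = np.repeat(["a", "b", "c"], 5)
        meta = pd.DataFrame(
            {"g": grp}, index=pd.Index([f"s{i}" for i in range(15)], name="sample")
        )
        y = rng.normal(size=15) + np.repeat([0.0, 1.0, 3.0], 5)
        d1 = build_design(meta, ModelSpec(fixed=["g"]))
        f1 = fit_gene(y, np.ones(15), d1.X, columns=d1.columns)
        # difference c - b via contrast on reference-a coding
        L = np.array([0.0, -1.0, 1.0])
        est1, se1, _ = contrast_test(f1, L)
        d2 = build_design(meta, ModelSpec(fixed=["g"], reference={"g": "b"}))
        f2 = fit_gene(y, np.ones(15), d2.X, columns=d2.columns)
        j = d2.columns.index("g[c]")
        np.testing.assert_allclose(est1, f2.beta[j], atol=1e-10)
        np.testing.assert_allclose(se1, f2.se[j], atol=1e-10)


class TestFitCluster:
    def _setup(self, n_genes=40, seed=8):
        rng = np.random.default_rng(seed)
        n = 12
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample")
        meta = pd.DataFrame(
            {
                "diagnosis": ["case"] * 6 + ["control"] * 6,
                "batch": ["b1", "b2", "b3"] * 4,
            },
            index=idx,
        )
        E = pd.DataFrame(
            rng.normal(size=(n, n_genes)),
            index=idx,
            columns=[f"g{j}" for j in range(n_genes)],
        )
        W = pd.DataFrame(
            rng.uniform(0.5, 2, size=(n, n_genes)), index=idx, columns=E.columns
        )
        lib = pd.Series(np.full(n, 1e6), index=idx, name="lib_size")
        return LogExpression(E=E, lib_size=lib), W, meta

    def test_worker_count_does_not_change_results(self):
        expr, W, meta = self._setup()
        spec = ModelSpec(fixed=["diagnosis"], random=["batch"], coef="diagnosis[control]")
        r1 = fit_cluster(expr, W, spec, meta, workers=1)
        r2 = fit_cluster(expr, W, spec, meta, workers=2)
        for f1, f2 in zip(r1.fits, r2.fits):
            np.testing.assert_array_equal(f1.beta, f2.beta)
            assert f1.varcomp == f2.varcomp

    def test_failed_gene_is_flagged_not_fatal(self):
        expr, W, meta = self._setup()
        E = expr.E.copy()
        E["g0"] = 3.14  # constant gene: zero residual variance
        expr2 = LogExpression(E=E, lib_size=expr.lib_size)
        spec = ModelSpec(fixed=["diagnosis"], coef="diagnosis[control]")
        res = fit_cluster(expr2, W, spec, meta)
        assert len(res.fits) == E.shape[1]
        assert res.converged_mask().sum() >= E.shape[1] - 1

    def test_null_simulation_t_symmetric_about_zero(self):
        expr, W, meta = self._setup(n_genes=500, seed=9)
        spec = ModelSpec(fixed=["diagnosis"], coef="diagnosis[control]")
        res = fit_cluster(expr, W, spec, meta)
        L = res.design.contrast_for(spec)
        ts = np.array([contrast_test(f, L)[2] for f in res.fits if f.converged])
        assert abs(ts.mean()) < 3 * ts.std() / np.sqrt(len(ts))
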