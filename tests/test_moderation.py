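import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from pblmm.moderation import (
    EBPrior,
    adjust_fdr,
    estimate_prior,
    moderate,
    residual_df,
)
from pblmm.regression import fit_gene
from pblmm.regression import test_contrast as contrast_test


def _random_intercept_design(rng, n_subj, reps, p_extra=1):
    n = n_subj * reps
    subj = np.repeat(np.arange(n_subj), reps)
    Z = np.zeros((n, n_subj))
    Z[np.arange(n), subj] = 1.0
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p_extra))])
    return X, Z, subj


class TestResidualDf:
    def test_exactly_n_minus_p_for_weighted_linear_models(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            p = int(rng.integers(1, min(n - 2, 6)))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) if p > 1 else np.ones((n, 1))
            w = rng.uniform(0.1, 10, size=n)
            fit = fit_gene(rng.normal(size=n), w, X)
            info = residual_df(fit, X, None, w)
            assert info.df_resid == pytest.approx(n - p, abs=1e-10)

    def test_continuity_at_zero_variance_boundary(self):
        rng = np.random.default_rng(11)
        X, Z, _ = _random_intercept_design(rng, 6, 2)
        n, p = X.shape
        e = rng.normal(0, 1, 6)
        y = X @ [1.0, 0.2] + np.column_stack([e, -e]).ravel()  # boundary fit
        w = rng.uniform(0.5, 2, size=n)
        fit = fit_gene(y, w, X, {"s": Z})
        assert fit.varcomp["s"] < 1e-6
        info = residual_df(fit, X, {"s": Z}, w)
        assert info.df_resid == pytest.approx(n - p, abs=1e-6)

    def test_df_decreases_to_within_subject_contrasts_along_variance_grid(self):
        """As the subject variance dominates, df falls from n - p toward
        n - rank([X Z]) monotonically (the number of residual contrasts that
        remain informative about the unit-level variance)."""
        rng = np.random.default_rng(12)
        X, Z, subj = _random_intercept_design(rng, 5, 2)
        n, p = X.shape
        w = np.ones(n)
        dfs = []
        for s2 in [0.1, 1.0, 10.0, 100.0, 10000.0]:
            y = X @ [1.0, 0.5] + np.sqrt(s2) * rng.standard_normal(5)[subj] + rng.normal(size=n)
            fit = fit_gene(y, w, X, {"s": Z})
            dfs.append(residual_df(fit, X, {"s": Z}, w).df_resid)
        assert all(d < n - p + 1e-9 for d in dfs)
        rank_xz = np.linalg.matrix_rank(np.column_stack([X, Z]))
        assert dfs[-1] == pytest.approx(n - rank_xz, abs=0.05)

    def test_mixture_weights_sum_to_df(self):
        rng = np.random.default_rng(13)
        X, Z, subj = _random_intercept_design(rng, 6, 3)
        n = X.shape[0]
        y = rng.normal(0, 1.5, 6)[subj] + rng.normal(size=n)
        w = rng.uniform(0.5, 2, size=n)
        fit = fit_gene(y, w, X, {"s": Z})
        info = residual_df(fit, X, {"s": Z}, w, full_spectrum=True)
        assert info.lambdas is not None
        assert (info.lambdas >= -1e-12).all()
        assert info.lambdas.sum() == pytest.approx(info.df_resid, abs=1e-8)

    def test_nonconverged_fit_rejected(self):
        rng = np.random.default_rng(14)
        X = np.ones((5, 1))
        fit = fit_gene(rng.normal(size=5), np.ones(5), X)
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            residual_df(fit, X, None, np.ones(5))


class TestEstimatePrior:
    def test_homogeneous_variances_give_infinite_prior_df(self):
        prior = estimate_prior(np.full(20, 4.0), np.full(20, 10.0))
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(4.0, rel=1e-6)

    def test_recovers_known_hyperparameters(self):
        rng = np.random.default_rng(15)
        d0, s0, df = 10.0, 2.0, 20.0
        sig2 = s0 * d0 / rng.chisquare(d0, size=20000)
        s2 = sig2 * rng.chisquare(df, size=20000) / df
        prior = estimate_prior(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0, rel=0.05)

    def test_two_gene_case_matches_numeric_moment_solve(self):
        from scipy.optimize import brentq
        from scipy.special import digamma, polygamma

        s2 = np.array([1.0, 100.0])
        df = np.array([5.0, 5.0])
        prior = estimate_prior(s2, df)
        assert 0 < prior.d0 < np.inf
        assert 1.0 < prior.s0_sq < 100.0
        e = np.log(s2) - digamma(df / 2) + np.log(df / 2)
        target = e.var(ddof=1) - polygamma(1, df[0] / 2)
        d0_direct = 2 * brentq(lambda x: polygamma(1, x) - target, 1e-6, 1e6)
        assert prior.d0 == pytest.approx(d0_direct, rel=1e-6)
        s0_direct = np.exp(e.mean() + digamma(d0_direct / 2) - np.log(d0_direct / 2))
        assert prior.s0_sq == pytest.approx(s0_direct, rel=1e-6)

    def test_matches_limma_reference_implementation(self, tmp_path):
        """Independent oracle: limma's lmFit + eBayes via Rscript on a fixture
        with heterogeneous gene variances (finite prior df)."""
        rng = np.random.default_rng(7)
        n, G = 8, 80
        X = np.column_stack([np.ones(n), np.repeat([0, 1], 4)])
        sig = np.sqrt(2.0 * 6 / rng.chisquare(6, size=G))
        Y = rng.normal(size=(G, n)) * sig[:, None]
        np.savetxt(tmp_path / "y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", X, delimiter=",")
        rcode = f"""
        suppressMessages(library(limma))
        Y <- as.matrix(read.csv('{tmp_path}/y.csv', header=FALSE))
        X <- as.matrix(read.csv('{tmp_path}/x.csv', header=FALSE))
        eb <- eBayes(lmFit(Y, X))
        out <- data.frame(d0=eb$df.prior, s0=eb$s2.prior, t=eb$t[,2],
                          p=eb$p.value[,2], s2post=eb$s2.post)
        write.csv(out, '{tmp_path}/ref.csv', row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv")

        fits = [fit_gene(Y[g], np.ones(n), X) for g in range(G)]
        est = np.array([f.beta[1] for f in fits])
        se = np.array([f.se[1] for f in fits])
        s2 = np.array([f.sigma2 for f in fits])
        df = np.array([f.df_resid for f in fits])
        prior = estimate_prior(s2, df)
        assert prior.d0 == pytest.approx(ref["d0"][0], rel=1e-5)
        assert prior.s0_sq == pytest.approx(ref["s0"][0], rel=1e-5)
        t, p, s2post, _ = moderate(est, se, s2, df, prior)
        np.testing.assert_allclose(t, ref["t"], atol=1e-8)
        np.testing.assert_allclose(p, ref["p"], atol=1e-8)
        np.testing.assert_allclose(s2post, ref["s2post"], atol=1e-8)


class TestModerate:
    def test_no_shrinkage_limit_recovers_raw_t_with_normal_reference(self):
        from scipy.stats import norm

        est = np.array([1.0, -0.5])
        se = np.array([0.5, 0.25])
        s2 = np.array([2.0, 2.0])
        df = np.array([8.0, 8.0])
        prior = EBPrior(d0=np.inf, s0_sq=2.0)
        t, p, s2post, dft = moderate(est, se, s2, df, prior)
        np.testing.assert_allclose(t, est / se)
        np.testing.assert_allclose(p, 2 * norm.sf(np.abs(est / se)))
        assert np.isinf(dft).all()

    def test_hand_computed_three_gene_oracle(self):
        from scipy.stats import t as t_dist

        est = np.array([0.8, -1.2, 0.1])
        se = np.array([0.4, 0.5, 0.2])
        s2 = np.array([1.0, 4.0, 0.25])
        df = np.array([6.0, 6.0, 6.0])
        prior = EBPrior(d0=4.0, s0_sq=1.5)
        t, p, s2post, dft = moderate(est, se, s2, df, prior)
        expected_post = (4.0 * 1.5 + 6.0 * s2) / 10.0
        np.testing.assert_allclose(s2post, expected_post)
        expected_t = (est / se) / np.sqrt(expected_post / s2)
        np.testing.assert_allclose(t, expected_t)
        np.testing.assert_allclose(p, 2 * t_dist.sf(np.abs(expected_t), 10.0))

    def test_posterior_variance_is_convex_combination(self):
        rng = np.random.default_rng(16)
        s2 = rng.uniform(0.1, 10, size=200)
        df = rng.uniform(3, 30, size=200)
        prior = EBPrior(d0=5.0, s0_sq=2.0)
        _, _, s2post, _ = moderate(np.ones(200), np.ones(200), s2, df, prior)
        lo = np.minimum(s2, prior.s0_sq) - 1e-12
        hi = np.maximum(s2, prior.s0_sq) + 1e-12
        assert ((s2post >= lo) & (s2post <= hi)).all()

    def test_moderated_p_uniform_under_full_null(self):
        """2,000 null genes through the WLS + EB pipeline: p-values uniform."""
        rng = np.random.default_rng(17)
        n, G = 12, 2000
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        sig = np.sqrt(1.0 * 8 / rng.chisquare(8, size=G))
        est, se, s2, df = [], [], [], []
        for g in range(G):
            y = rng.normal(0, sig[g], size=n)
            f = fit_gene(y, np.ones(n), X)
            e, s, _ = contrast_test(f, np.array([0.0, 1.0]))
            est.append(e)
            se.append(s)
            s2.append(f.sigma2)
            df.append(f.df_resid)
        prior = estimate_prior(np.array(s2), np.array(df))
        _, p, _, _ = moderate(
            np.array(est), np.array(se), np.array(s2), np.array(df), prior
        )
        assert kstest(p, "uniform").statistic < 0.05


class TestAdjustFdr:
    @staticmethod
    def _frame(ps, clusters=None):
        return pd.DataFrame(
            {
                "cluster": clusters or ["c"] * len(ps),
                "gene": [f"g{i}" for i in range(len(ps))],
                "P.Value": ps,
            }
        )

    def test_single_test_unchanged(self):
        out = adjust_fdr(self._frame([0.01]))
        assert out["adj.P.Val"][0] == pytest.approx(0.01)

    def test_step_up_arithmetic(self):
        out = adjust_fdr(self._frame([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(out["adj.P.Val"], [0.03, 0.03, 0.03])

    def test_matches_brute_force_bh(self):
        rng = np.random.default_rng(18)
        ps = rng.uniform(size=57)
        out = adjust_fdr(self._frame(ps))["adj.P.Val"].to_numpy()
        m = len(ps)
        order = np.argsort(ps)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, ps[idx] * m / rank)
            brute[idx] = running
        np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_study_wide_scope_pools_clusters(self):
        ps = [0.001, 0.5, 0.002, 0.6]
        clusters = ["c1", "c1", "c2", "c2"]
        study = adjust_fdr(self._frame(ps, clusters), scope="study")
        per = adjust_fdr(self._frame(ps, clusters), scope="cluster")
        assert study["adj.P.Val"][0] == pytest.approx(0.004)
        assert per["adj.P.Val"][0] == pytest.approx(0.002)

    def test_null_pvalues_rarely_yield_discoveries(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = adjust_fdr(self._frame(rng.uniform(size=1000)))
            if (out["adj.P.Val"] < 0.05).sum() == 0:
                hits += 1
        # P(no BH discovery under 1000 independent uniforms) ~ 0.945;
        # 90 is > 3 binomial sd below that expectation
        assert hits >= 90
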