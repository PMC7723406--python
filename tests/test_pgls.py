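"""Tree handling, phylogenetic covariances, GLS fits and LRTs."""

import math

import numpy as np
import pandas as pd
import pytest

import radmut
from radmut import pgls

from conftest import random_ultrametric_tree


class TestParseTree:
    def test_three_taxon_chronogram(self, three_taxon_tree):
        assert sorted(pgls.tip_labels(three_taxon_tree)) == ["A", "B", "C"]
        assert pgls.tree_depth(three_taxon_tree) == pytest.approx(2.0)
        assert pgls.ultrametricity_spread(three_taxon_tree) == pytest.approx(0.0)

    def test_non_ultrametric_reported(self):
        with pytest.raises(pgls.TreeError, match="not ultrametric"):
            pgls.parse_tree("((A:1,B:2):1,C:2);")
        tree = pgls.parse_tree("((A:1,B:2):1,C:2);", check_ultrametric=False)
        assert pgls.ultrametricity_spread(tree) == pytest.approx(1.0)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(pgls.TreeError, match="duplicate"):
            pgls.parse_tree("((A:1,A:1):1,C:2);")

    def test_malformed_rejected(self):
        with pytest.raises(pgls.TreeError):
            pgls.parse_tree("((A:1,B:1:1,C;")

    def test_prune_merges_paths(self, three_taxon_tree):
        pruned = pgls.prune_tips(three_taxon_tree, ["C"])
        assert sorted(pgls.tip_labels(pruned)) == ["A", "B"]
        v = pgls.brownian_vcv(pruned, labels=["A", "B"]).matrix
        # tip depths are preserved after merging the basal path
        assert np.allclose(np.diag(v), 2.0)
        assert v[0, 1] == pytest.approx(1.0)

    def test_prune_below_two_tips_rejected(self, three_taxon_tree):
        with pytest.raises(pgls.TreeError):
            pgls.prune_tips(three_taxon_tree, ["A", "B"])


class TestBrownianVCV:
    def test_hand_computed_matrix(self, three_taxon_tree):
        v = pgls.brownian_vcv(three_taxon_tree, labels=["A", "B", "C"]).matrix
        assert np.allclose(v, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree(self):
        tree = pgls.parse_tree("(A:3,B:3,C:3,D:3);")
        v = pgls.brownian_vcv(tree).matrix
        assert np.allclose(v, 3 * np.eye(4))

    def test_symmetric_psd_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            tree = random_ultrametric_tree(rng)
            v = pgls.brownian_vcv(tree).matrix
            assert np.allclose(v, v.T)
            np.linalg.cholesky(v)  # PD without jitter


class TestCorrelationTransform:
    def test_pagel_limits(self, three_taxon_tree):
        vcv = pgls.brownian_vcv(three_taxon_tree)
        same = pgls.correlation_transform(vcv, "pagel", 1.0).matrix
        assert np.allclose(same, vcv.matrix)
        diag = pgls.correlation_transform(vcv, "pagel", 0.0).matrix
        assert np.allclose(diag, np.diag(np.diag(vcv.matrix)))

    def test_martins_zero_alpha_gives_full_correlation(self, three_taxon_tree):
        vcv = pgls.brownian_vcv(three_taxon_tree)
        out = pgls.correlation_transform(vcv, "martins", 0.0).matrix
        d = np.sqrt(np.diag(out))
        assert np.allclose(out / np.outer(d, d), 1.0)

    def test_blomberg_small_g_approaches_brownian(self, three_taxon_tree):
        vcv = pgls.brownian_vcv(three_taxon_tree)
        out = pgls.correlation_transform(vcv, "blomberg", 1e-8).matrix
        assert np.allclose(out, vcv.matrix, rtol=1e-6)

    def test_parameter_ranges(self, three_taxon_tree):
        vcv = pgls.brownian_vcv(three_taxon_tree)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            pgls.correlation_transform(vcv, "pagel", 1.5)
        with pytest.raises(ValueError, match=">= 0"):
            pgls.correlation_transform(vcv, "martins", -1.0)
        with pytest.raises(ValueError, match="nonzero"):
            pgls.correlation_transform(vcv, "blomberg", 0.0)


def _ols_loglik(y, X):
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    s2 = rss / n
    return beta, -0.5 * n * math.log(2 * math.pi * s2) - 0.5 * n


class TestFitGLS:
    def test_identity_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        n = 10
        table = pd.DataFrame(
            {"y": rng.normal(size=n), "x": rng.normal(size=n)},
            index=[f"t{i}" for i in range(n)],
        )
        fit = pgls.fit_gls(table, "y", ["x"], np.eye(n))
        X = np.column_stack([np.ones(n), table["x"]])
        beta, loglik = _ols_loglik(table["y"].to_numpy(), X)
        assert np.allclose(fit.beta, beta)
        assert fit.loglik == pytest.approx(loglik)

    def test_diagonal_weighted_hand_solution(self):
        """y=[1,2,3], x=[0,1,2], V=diag(1,1,4): explicit 2x2 normal equations."""
        table = pd.DataFrame({"y": [1.0, 2, 3], "x": [0.0, 1, 2]},
                             index=["a", "b", "c"])
        fit = pgls.fit_gls(table, "y", ["x"], np.diag([1.0, 1.0, 4.0]))
        # weighted normal equations with weights w = 1/diag(V):
        w = np.array([1.0, 1.0, 0.25])
        x = table["x"].to_numpy()
        y = table["y"].to_numpy()
        a11, a12 = w.sum(), (w * x).sum()
        a22 = (w * x * x).sum()
        b1, b2 = (w * y).sum(), (w * x * y).sum()
        det = a11 * a22 - a12 * a12
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (a11 * b2 - a12 * b1) / det
        assert fit.beta == pytest.approx([beta0, beta1])
        assert fit.beta == pytest.approx([1.0, 1.0])

    def test_constant_response(self, three_taxon_tree):
        vcv = pgls.brownian_vcv(three_taxon_tree)
        table = pd.DataFrame({"y": [5.0, 5, 5], "x": [0.0, 1, 2]},
                             index=vcv.labels)
        fit = pgls.fit_gls(table, "y", ["x"], vcv)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.beta[0] == pytest.approx(5.0)

    def test_whitened_ols_oracle_equivalence(self):
        """GLS coefficients match OLS on Cholesky-whitened data to 1e-10."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            tree = random_ultrametric_tree(rng, n_pairs=3, n_extra=2)
            labels = pgls.tip_labels(tree)
            vcv = pgls.brownian_vcv(tree, labels=labels)
            n = len(labels)
            table = pd.DataFrame(
                {"y": rng.normal(size=n), "x": rng.normal(size=n)}, index=labels
            )
            fit = pgls.fit_gls(table, "y", ["x"], vcv)
            L = np.linalg.cholesky(vcv.matrix)
            Xw = np.linalg.solve(L, np.column_stack([np.ones(n), table["x"]]))
            yw = np.linalg.solve(L, table["y"].to_numpy())
            beta_ols, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            assert np.abs(fit.beta - beta_ols).max() < 1e-10

    def test_rejects_reml_and_singular(self, three_taxon_tree):
        vcv = pgls.brownian_vcv(three_taxon_tree)
        table = pd.DataFrame({"y": [1.0, 2, 3], "x": [1.0, 1, 1]}, index=vcv.labels)
        with pytest.raises(pgls.EstimationError, match="ML"):
            pgls.fit_gls(table, "y", ["x"], vcv, method="REML")
        with pytest.raises(pgls.EstimationError, match="singular"):
            pgls.fit_gls(table, "y", ["x"], vcv)  # x collinear with intercept


class TestLRT:
    def _fits(self, rng, n=12, beta=0.8):
        labels = [f"t{i}" for i in range(n)]
        x = rng.normal(size=n)
        y = 1.0 + beta * x + rng.normal(size=n)
        table = pd.DataFrame({"y": y, "x": x}, index=labels)
        V = np.eye(n)
        return pgls.fit_gls(table, "y", ["x"], V), pgls.fit_gls(table, "y", [], V)

    def test_self_comparison_rejected(self):
        rng = np.random.default_rng(4)
        full, _ = self._fits(rng)
        with pytest.raises(pgls.EstimationError, match="more parameters"):
            pgls.lrt(full, full)

    def test_equivalent_fits_give_zero_statistic(self):
        """A predictor with an exactly-zero coefficient: Lambda=0, p=1, R2=0."""
        table = pd.DataFrame({"y": [1.0, 2, 1], "x": [-1.0, 0, 1]},
                             index=["a", "b", "c"])
        full = pgls.fit_gls(table, "y", ["x"], np.eye(3))
        null = pgls.fit_gls(table, "y", [], np.eye(3))
        assert full.slope == pytest.approx(0.0, abs=1e-12)
        res = pgls.lrt(full, null)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)
        assert res.cox_snell_r2 == pytest.approx(0.0, abs=1e-10)

    def test_cox_snell_identity(self):
        rng = np.random.default_rng(8)
        full, null = self._fits(rng)
        res = pgls.lrt(full, null)
        # R2 from (Lambda, n) equals 1 - (L_null/L_full)^(2/n)
        ratio_form = 1.0 - math.exp(null.loglik - full.loglik) ** (2.0 / full.n)
        assert res.cox_snell_r2 == pytest.approx(ratio_form, abs=1e-12)

    def test_contract_errors(self):
        rng = np.random.default_rng(5)
        full, null = self._fits(rng)
        with pytest.raises(pgls.EstimationError, match="nested"):
            pgls.lrt(null, full)

    def test_model_robustness_harness(self, small_dataset):
        table = small_dataset.covariates.copy()
        table["log_alpha"] = np.log(table["alpha_radio"])
        table["y"] = np.log(table["ds_ra"])
        frame = radmut.model_robustness(table, small_dataset.tree, "y", "log_alpha")
        assert len(frame) == 4
        assert set(frame["model"]) == {"brownian", "pagel", "martins", "blomberg"}
        assert frame["l_ratio"].ge(0).all()


class TestJackknife:
    def test_duplicated_observations_on_star_tree(self):
        tree = pgls.parse_tree("(A:1,B:1,C:1,D:1,E:1,F:1);")
        x = np.array([0.0, 1, 2, 0, 1, 2])
        table = pd.DataFrame({"y": 1 + 2 * x + np.tile([0.05, -0.05, 0.0], 2),
                              "x": x},
                             index=pgls.tip_labels(tree))
        jk = radmut.jackknife_fits(table, tree, "y", "x")
        assert len(jk) == 6
        full_slope = pgls.pgls_lrt(table, tree, "y", "x")["slope"]
        # leaving out one copy of a duplicated design point barely moves the slope
        assert np.allclose(jk["slope"], full_slope, atol=0.15)

    def test_engineered_outlier_is_most_influential(self, small_dataset):
        table = small_dataset.covariates.copy()
        table["x"] = np.log(table["alpha_radio"])
        rng = np.random.default_rng(12)
        table["y"] = 0.5 * table["x"] + 0.05 * rng.normal(size=len(table))
        outlier = table.index[0]
        table.loc[outlier, "y"] += 3.0
        full_slope = pgls.pgls_lrt(table, small_dataset.tree, "y", "x")["slope"]
        jk = radmut.jackknife_fits(table, small_dataset.tree, "y", "x")
        change = (jk["slope"] - full_slope).abs()
        assert jk.loc[change.idxmax(), "left_out"] == outlier

    def test_too_few_tips(self, three_taxon_tree):
        table = pd.DataFrame({"y": [1.0, 2, 3], "x": [0.0, 1, 2]},
                             index=["A", "B", "C"])
        with pytest.raises(pgls.EstimationError, match="4 tips"):
            radmut.jackknife_fits(table, three_taxon_tree, "y", "x")


class TestResidualDiagnostics:
    def test_identity_covariance_keeps_raw_residuals(self):
        rng = np.random.default_rng(6)
        n = 15
        table = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)},
                             index=[f"t{i}" for i in range(n)])
        fit = pgls.fit_gls(table, "y", ["x"], np.eye(n))
        diag = radmut.residual_diagnostics(fit, np.eye(n))
        assert np.allclose(diag["whitened_residuals"], fit.residuals)
        assert 0 <= diag["shapiro_p"] <= 1

    def test_perfect_fit_zero_residuals(self):
        table = pd.DataFrame({"y": [1.0, 2, 3], "x": [0.0, 1, 2]},
                             index=["a", "b", "c"])
        fit = pgls.fit_gls(table, "y", ["x"], np.eye(3))
        diag = radmut.residual_diagnostics(fit, np.eye(3))
        assert np.allclose(diag["whitened_residuals"], 0.0)

    def test_shapiro_p_close_to_uniform_under_gaussian_noise(self, three_taxon_tree):
        """Shapiro p over replicates is close to uniform for Gaussian data."""
        rng = np.random.default_rng(13)
        tree = pgls.parse_tree(
            "(" + ",".join(f"t{i}:1" for i in range(25)) + ");"
        )
        n = 25
        V = np.eye(n)
        pvals = []
        for _ in range(400):
            table = pd.DataFrame(
                {"y": rng.normal(size=n), "x": rng.normal(size=n)},
                index=[f"t{i}" for i in range(n)],
            )
            fit = pgls.fit_gls(table, "y", ["x"], V)
            pvals.append(radmut.residual_diagnostics(fit, V)["shapiro_p"])
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3
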