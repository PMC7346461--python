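"""Comparative statistics: contrasts, signal, GLS, ANOVA, pPCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from snakedent import (
    TreeError,
    parse_newick,
    pgls,
    phyl_anova,
    phyl_resid,
    phylo_signal_K,
    phylo_signal_lambda,
    pic,
    pic_regression,
    ppca,
    sim_bm_trait,
    sim_yule_tree,
    vcv_matrix,
)


class TestPIC:
    def test_two_tip_contrast(self):
        t = parse_newick("(A:1,B:1);")
        np.testing.assert_allclose(pic(t, {"A": 3, "B": 1}), [2 / np.sqrt(2)])

    def test_equal_values_give_zero_contrasts(self, yule20):
        assert np.allclose(pic(yule20, np.full(20, 7.0)), 0.0)

    def test_hand_pruned_three_tip_case(self, three_tip_tree):
        contrasts = pic(three_tip_tree, {"A": 1, "B": 3, "C": 6})
        np.testing.assert_allclose(contrasts, [-1.41421356, -2.13808994], atol=1e-8)

    def test_polytomy_rejected(self):
        star = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="polytomy"):
            pic(star, {"A": 1, "B": 2, "C": 3})

    def test_missing_tip_value_names_species(self, three_tip_tree):
        with pytest.raises(ValueError, match="C"):
            pic(three_tip_tree, {"A": 1.0, "B": 2.0})

    def test_contrasts_standard_normal_under_bm(self):
        """Contrasts under Brownian motion are ~N(0, sigma^2)."""
        tree = sim_yule_tree(64, seed=7)
        sigma2 = 2.5
        all_c = np.concatenate(
            [
                pic(tree, sim_bm_trait(tree, sigma2=sigma2, seed=1000 + i))
                for i in range(200)
            ]
        )
        assert abs(all_c.mean()) < 3 * all_c.std() / np.sqrt(all_c.size)
        assert all_c.var() == pytest.approx(sigma2, rel=0.05)


class TestPICRegression:
    def test_exact_proportionality(self):
        cx = np.array([1.0, -2.0, 0.5, 3.0])
        res = pic_regression(cx, 2 * cx)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_contrasts_slope_zero(self):
        cx = np.array([1.0, -1.0, 1.0, -1.0])
        cy = np.array([1.0, 1.0, -1.0, -1.0])
        assert pic_regression(cx, cy).slope == pytest.approx(0.0)

    def test_zero_predictor_rejected(self):
        with pytest.raises(ValueError):
            pic_regression(np.zeros(5), np.ones(5))

    def test_pic_slope_equals_gls_slope(self):
        """Through-origin contrast regression = GLS slope with intercept."""
        for i in range(10):
            tree = sim_yule_tree(20, seed=900 + i)
            x = sim_bm_trait(tree, seed=2 * i)
            y = sim_bm_trait(tree, seed=2 * i + 1)
            slope_pic = pic_regression(pic(tree, x), pic(tree, y)).slope
            slope_gls = pgls(tree, y, x).slope
            assert slope_pic == pytest.approx(slope_gls, abs=1e-8)


class TestLambdaSignal:
    def test_lambda0_likelihood_is_iid_normal(self, yule20):
        """On an ultrametric tree the lambda = 0 model is iid normal."""
        x = sim_bm_trait(yule20, seed=3).to_numpy()
        res = phylo_signal_lambda(yule20, x)
        n = x.size
        s2 = x.var()
        iid_logL = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        # absorb the (constant) tree-height variance scale
        h = yule20.height
        iid_logL_scaled = iid_logL  # MLE variance absorbs h exactly
        assert res.log_likelihood_lambda0 == pytest.approx(iid_logL_scaled, abs=1e-9)

    def test_constant_trait_rejected(self, yule20):
        with pytest.raises(ValueError, match="constant"):
            phylo_signal_lambda(yule20, np.ones(20))

    def test_recovery_under_bm(self):
        tree = sim_yule_tree(100, seed=5)
        lams = [
            phylo_signal_lambda(tree, sim_bm_trait(tree, lam=1.0, seed=i)).lam
            for i in range(20)
        ]
        assert np.mean(lams) > 0.85

    def test_near_zero_for_iid_data(self):
        tree = sim_yule_tree(100, seed=6)
        rng = np.random.default_rng(0)
        lams = [
            phylo_signal_lambda(tree, rng.standard_normal(100)).lam for _ in range(10)
        ]
        assert np.mean(lams) < 0.2


class TestKSignal:
    def test_min_p_with_999_permutations(self, yule20):
        res = phylo_signal_K(yule20, sim_bm_trait(yule20, seed=4), nperm=999, seed=0)
        assert res.p_K >= 1 / 1000

    def test_nperm_floor(self, yule20):
        with pytest.raises(ValueError):
            phylo_signal_K(yule20, sim_bm_trait(yule20, seed=4), nperm=10)

    def test_k_near_one_under_bm(self):
        tree = sim_yule_tree(64, seed=9)
        ks = [
            phylo_signal_K(tree, sim_bm_trait(tree, seed=i), nperm=99, seed=i).K
            for i in range(50)
        ]
        assert 0.85 < np.mean(ks) < 1.15


class TestGLS:
    def test_affine_response_gives_zero_residuals(self, yule20):
        x = sim_bm_trait(yule20, seed=11)
        y = 3.0 + 2.0 * x
        assert np.allclose(phyl_resid(yule20, y, x), 0.0, atol=1e-10)

    def test_star_tree_reduces_to_ols(self):
        star = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=star.tip_labels)
        y = pd.Series([2.1, 3.9, 6.2, 7.8, 10.1], index=star.tip_labels)
        res = pgls(star, y, x)
        slope_ols, intercept_ols = np.polyfit(x.to_numpy(), y.to_numpy(), 1)
        assert res.slope == pytest.approx(slope_ols, abs=1e-8)
        assert res.intercept == pytest.approx(intercept_ols, abs=1e-8)
        ols_resid = y.to_numpy() - (intercept_ols + slope_ols * x.to_numpy())
        np.testing.assert_allclose(res.residuals.to_numpy(), ols_resid, atol=1e-8)

    def test_five_tip_matches_matrix_inversion_oracle(self):
        tree = parse_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        x = pd.Series([0.2, 1.1, -0.4, 2.0, 1.5], index=tree.tip_labels)
        y = pd.Series([1.0, 2.5, 0.3, 3.9, 3.1], index=tree.tip_labels)
        C = vcv_matrix(tree).matrix
        X = np.column_stack([np.ones(5), x.to_numpy()])
        Ci = linalg.inv(C)
        beta = linalg.inv(X.T @ Ci @ X) @ X.T @ Ci @ y.to_numpy()
        oracle = y.to_numpy() - X @ beta
        np.testing.assert_allclose(
            phyl_resid(tree, y, x).to_numpy(), oracle, atol=1e-10
        )

    def test_phyl_resid_equals_pgls_residuals(self, yule20):
        x = sim_bm_trait(yule20, seed=12)
        y = sim_bm_trait(yule20, seed=13)
        np.testing.assert_array_equal(
            phyl_resid(yule20, y, x).to_numpy(),
            pgls(yule20, y, x).residuals.to_numpy(),
        )

    def test_exact_linear_relationship(self, yule20):
        x = sim_bm_trait(yule20, seed=14)
        res = pgls(yule20, 1.0 + 0.5 * x, x)
        assert res.r_squared == pytest.approx(1.0)

    def test_slope_recovery_under_bm(self):
        tree = sim_yule_tree(100, seed=20)
        b = 0.7
        slopes = []
        for i in range(30):
            x = sim_bm_trait(tree, seed=3000 + i)
            noise = sim_bm_trait(tree, sigma2=0.25, seed=4000 + i)
            slopes.append(pgls(tree, b * x + noise, x).slope)
        assert np.mean(slopes) == pytest.approx(b, abs=0.05)

    def test_ml_lambda_mode_runs(self, yule20):
        x = sim_bm_trait(yule20, seed=15)
        y = 0.5 * x + sim_bm_trait(yule20, sigma2=0.3, seed=16)
        res = pgls(yule20, y, x, lambda_mode="ML")
        assert 0.0 <= res.lam <= 1.0


class TestPhylANOVA:
    def test_classical_f_on_toy(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = phyl_anova(
            tree,
            {"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0},
            {"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
            nsim=100,
            seed=0,
        )
        assert res.F == pytest.approx(8.0)
        assert res.group_means == {"g1": 0.5, "g2": 2.5}

    def test_saturated_effect_hits_minimum_p(self):
        tree = sim_yule_tree(40, seed=30)
        x = sim_bm_trait(tree, sigma2=0.01, seed=31)
        groups = {s: ("a" if i < 20 else "b") for i, s in enumerate(tree.tip_labels)}
        x = x + pd.Series({s: (0.0 if g == "a" else 50.0) for s, g in groups.items()})
        res = phyl_anova(tree, x, groups, nsim=500, seed=32)
        assert res.p_value == pytest.approx(1 / 501)

    def test_small_group_rejected(self, yule20):
        groups = {s: "a" for s in yule20.tip_labels}
        groups[yule20.tip_labels[0]] = "b"
        with pytest.raises(ValueError, match="fewer than 2"):
            phyl_anova(yule20, sim_bm_trait(yule20, seed=1), groups, nsim=100)

    def test_posthoc_antisymmetric_t(self):
        tree = sim_yule_tree(30, seed=33)
        x = sim_bm_trait(tree, seed=34)
        groups = {
            s: ("a", "b", "c")[i % 3] for i, s in enumerate(tree.tip_labels)
        }
        res = phyl_anova(tree, x, groups, nsim=200, seed=35)
        T = res.posthoc_t.to_numpy()
        np.testing.assert_allclose(T, -T.T, atol=1e-12)
        P = res.posthoc_p.to_numpy()
        np.testing.assert_allclose(P, P.T)


class TestPPCA:
    def test_single_trait_degenerate(self, yule20):
        x = sim_bm_trait(yule20, seed=40)
        res = ppca(yule20, x.to_frame("t"))
        assert abs(res.loadings.iloc[0, 0]) == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_trace(self, yule20):
        X = pd.DataFrame(
            {f"t{i}": sim_bm_trait(yule20, seed=50 + i) for i in range(4)}
        )
        res = ppca(yule20, X)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(res.R), abs=1e-8)
        res_corr = ppca(yule20, X, mode="correlation")
        assert res_corr.eigenvalues.sum() == pytest.approx(4.0, abs=1e-8)

    def test_score_gls_covariance_diagonal_is_eigenvalues(self, yule20):
        X = pd.DataFrame(
            {f"t{i}": sim_bm_trait(yule20, seed=60 + i) for i in range(3)}
        )
        res = ppca(yule20, X)
        C = vcv_matrix(yule20).matrix
        S = res.scores.to_numpy()
        G = S.T @ linalg.inv(C) @ S / (len(X) - 1)
        np.testing.assert_allclose(np.diag(G), res.eigenvalues, atol=1e-8)
        # scores reproduce the centered data under back-rotation
        np.testing.assert_allclose(
            S @ res.eigenvectors.T,
            X.loc[yule20.tip_labels].to_numpy() - res.mean,
            atol=1e-8,
        )

    def test_two_trait_eigen_oracle(self):
        tree = parse_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        X = pd.DataFrame(
            {"u": [0.1, 0.9, -0.5, 1.7, 1.2], "v": [1.2, 0.3, 0.8, -0.2, 0.4]},
            index=tree.tip_labels,
        )
        res = ppca(tree, X)
        C = vcv_matrix(tree).matrix
        Ci = linalg.inv(C)
        one = np.ones(5)
        a = (one @ Ci @ X.to_numpy()) / (one @ Ci @ one)
        Xc = X.to_numpy() - a
        R = Xc.T @ Ci @ Xc / 4
        evals = np.sort(linalg.eigvalsh(R))[::-1]
        np.testing.assert_allclose(res.eigenvalues, evals, atol=1e-10)
        np.testing.assert_allclose(res.R, R, atol=1e-12)
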