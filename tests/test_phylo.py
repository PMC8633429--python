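import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oakwood import phylo, simulate


def _random_yule(n, seed):
    return simulate.yule_tree(n, np.random.default_rng(seed))


class TestTreeIO:
    def test_prune_collapses_unifurcations(self):
        tree = phylo.read_newick("((A:1,B:1):1,C:2);")
        pruned = phylo.prune(tree, ["A", "C"])
        labels, C = phylo.brownian_covariance(pruned)
        assert labels == ["A", "C"]
        np.testing.assert_allclose(np.diag(C), [2.0, 2.0])
        assert C[0, 1] == 0.0

    def test_prune_to_all_tips_is_identity(self):
        tree = phylo.read_newick("((A:1,B:1):0.5,(C:0.8,D:0.8):0.7);")
        pruned = phylo.prune(tree, ["A", "B", "C", "D"])
        _, C1 = phylo.brownian_covariance(tree)
        _, C2 = phylo.brownian_covariance(pruned)
        np.testing.assert_allclose(C1, C2)

    def test_roundtrip_write_read(self):
        tree = _random_yule(20, 5)
        text = phylo.write_newick(tree)
        back = phylo.read_newick(text)
        l1, C1 = phylo.brownian_covariance(tree)
        l2, C2 = phylo.brownian_covariance(back)
        assert l1 == l2
        np.testing.assert_allclose(C1, C2, atol=1e-9)

    def test_malformed_and_missing_lengths_error(self):
        with pytest.raises(ValueError):
            phylo.read_newick("((A:1,B:1")
        with pytest.raises(ValueError, match="branch length"):
            phylo.read_newick("((A:1,B),C:2);")

    def test_prune_unknown_tip_errors(self):
        tree = phylo.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="not in tree"):
            phylo.prune(tree, ["A", "Z"])

    def test_name_reconciliation(self):
        tree = phylo.read_newick("(Quercus_laeta:1,Quercus_resinosa:1);")
        tips = set(phylo.tip_labels(tree))
        mapping = phylo.reconcile_names(tree, ["quercus laeta", "QUERCUS RESINOSA"])
        assert set(mapping.values()) == tips
        with pytest.raises(ValueError, match="not matched"):
            phylo.reconcile_names(tree, ["quercus nope"])


class TestPIC:
    def test_single_cherry_formula(self):
        tree = phylo.read_newick("(A:1,B:1);")
        cs = phylo.pic(tree, {"A": 3.0, "B": 1.0})
        assert cs.contrasts[0] == pytest.approx(2 / np.sqrt(2))

    def test_constant_trait_all_zero(self):
        tree = _random_yule(10, 3)
        cs = phylo.pic(tree, {t: 7.0 for t in phylo.tip_labels(tree)})
        np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)
        assert len(cs.contrasts) == 9

    def test_through_origin_slope_matches_dense_gls(self):
        # PIC regression through the origin is algebraically a Brownian GLS fit
        tree = _random_yule(6, 11)
        rng = np.random.default_rng(2)
        labels, C = phylo.brownian_covariance(tree)
        x = pd.Series(rng.normal(size=6), index=labels)
        y = pd.Series(2.0 * x.to_numpy() + rng.normal(scale=0.3, size=6), index=labels)
        cx = phylo.pic(tree, x).contrasts
        cy = phylo.pic(tree, y).contrasts
        slope_pic = np.sum(cx * cy) / np.sum(cx**2)
        X = np.column_stack([np.ones(6), x.to_numpy()])
        gls = sm.GLS(y.to_numpy(), X, sigma=C).fit()
        assert slope_pic == pytest.approx(gls.params[1], rel=1e-10)

    def test_contrast_variance_calibrated_under_brownian(self):
        tree = _random_yule(40, 21)
        rng = np.random.default_rng(4)
        variances = []
        for _ in range(100):
            sim = phylo.simulate_bm(tree, rate=2.5, rng=rng)
            variances.append(phylo.pic(tree, sim["trait_1"]).variance)
        assert np.mean(variances) == pytest.approx(2.5, rel=0.15)

    def test_polytomy_resolution_toggle(self):
        tree = phylo.read_newick("(A:1,B:1,C:1);")
        cs = phylo.pic(tree, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert len(cs.contrasts) == 2
        with pytest.raises(ValueError, match="polytom"):
            phylo.pic(tree, {"A": 1.0, "B": 2.0, "C": 3.0}, resolve_polytomies=False)

    def test_missing_tip_value_errors(self):
        tree = phylo.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing"):
            phylo.pic(tree, {"A": 1.0})


class TestCorrelations:
    def test_self_correlation_unity(self, balanced_tree):
        df = pd.DataFrame(
            {"t1": [1.0, 2.0, 3.0, 4.0], "t2": [1.0, 2.0, 3.0, 4.0]},
            index=["A", "B", "C", "D"],
        )
        r, p = phylo.correlation_matrix(df, mode="raw")
        assert r.loc["t1", "t2"] == pytest.approx(1.0)
        r2, _ = phylo.correlation_matrix(df, mode="pic", tree=balanced_tree)
        assert r2.loc["t1", "t2"] == pytest.approx(1.0)

    def test_perfect_negative(self, balanced_tree):
        df = pd.DataFrame(
            {"t1": [1.0, 2.0, 3.0, 5.0], "t2": [-1.0, -2.0, -3.0, -5.0]},
            index=["A", "B", "C", "D"],
        )
        for mode, tree in (("raw", None), ("pic", balanced_tree)):
            r, _ = phylo.correlation_matrix(df, mode=mode, tree=tree)
            assert r.loc["t1", "t2"] == pytest.approx(-1.0)

    def test_pic_correlation_recovers_generating_value(self):
        # correlated Brownian traits, rho = 0.8
        tree = _random_yule(50, 31)
        rng = np.random.default_rng(6)
        rho = 0.8
        rs = []
        for _ in range(200):
            sim = phylo.simulate_bm(tree, rate=1.0, rng=rng, n_traits=2)
            a = sim["trait_1"]
            b = rho * sim["trait_1"] + np.sqrt(1 - rho**2) * sim["trait_2"]
            df = pd.DataFrame({"a": a, "b": b})
            r, _ = phylo.correlation_matrix(df, mode="pic", tree=tree)
            rs.append(r.loc["a", "b"])
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)

    def test_combined_table_layout(self, balanced_tree):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            rng.normal(size=(4, 3)), index=list("ABCD"), columns=["t1", "t2", "t3"]
        )
        combined = phylo.combined_correlation_table(df, balanced_tree)
        r_raw, _ = phylo.correlation_matrix(df, mode="raw")
        r_pic, _ = phylo.correlation_matrix(df, mode="pic", tree=balanced_tree)
        assert combined.loc["t2", "t1"] == r_raw.loc["t2", "t1"]
        assert combined.loc["t1", "t2"] == r_pic.loc["t1", "t2"]


class TestPCA:
    def test_perfectly_correlated_pair_single_component(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        res = phylo.pca(df)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_percent_variance_sums_to_100_and_order_invariant(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        res = phylo.pca(df)
        assert res.percent_variance.sum() == pytest.approx(100.0)
        res2 = phylo.pca(df[["c", "a", "e", "b", "d"]])
        np.testing.assert_allclose(
            sorted(res.percent_variance), sorted(res2.percent_variance), rtol=1e-9
        )

    def test_matches_svd_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 5)))
        res = phylo.pca(df, standardize=False)
        Xc = df.to_numpy() - df.to_numpy().mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        var = sv**2 / (len(df) - 1)
        np.testing.assert_allclose(
            res.percent_variance, 100 * var / var.sum(), rtol=1e-9
        )

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            phylo.pca(df)


class TestBlombergK:
    @staticmethod
    def _dense_k_oracle(tree, x_series):
        """Direct matrix-formula K with explicit Brownian covariance."""
        labels, C = phylo.brownian_covariance(tree)
        x = x_series.loc[labels].to_numpy()
        n = len(x)
        Cinv = np.linalg.inv(C)
        one = np.ones(n)
        ahat = one @ Cinv @ x / (one @ Cinv @ one)
        r = x - ahat
        ratio_obs = (r @ r) / (r @ Cinv @ r)
        ratio_exp = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
        return ratio_obs / ratio_exp

    def test_matches_dense_matrix_oracle(self):
        tree = _random_yule(5, 17)
        rng = np.random.default_rng(9)
        x = pd.Series(rng.normal(size=5), index=sorted(phylo.tip_labels(tree)))
        K = phylo.blomberg_k(tree, x, n_randomizations=0).K
        assert K == pytest.approx(self._dense_k_oracle(tree, x), rel=1e-10)

    def test_randomization_p_small_for_strong_signal(self, yule50):
        sim = phylo.simulate_bm(yule50, rate=1.0, seed=41)
        res = phylo.blomberg_k(yule50, sim["trait_1"], n_randomizations=199, seed=42)
        assert res.p_value < 0.05  # Brownian data on its own tree: clear signal

    def test_shuffled_trait_loses_signal(self, yule50):
        rng = np.random.default_rng(43)
        sim = phylo.simulate_bm(yule50, rate=1.0, rng=rng)["trait_1"]
        shuffled = pd.Series(
            rng.permutation(sim.to_numpy()), index=sim.index
        )
        res = phylo.blomberg_k(yule50, shuffled, n_randomizations=199, seed=44)
        assert res.K < 0.5

    def test_reproducible_given_seed(self, yule50):
        sim = phylo.simulate_bm(yule50, rate=1.0, seed=45)
        a = phylo.blomberg_k(yule50, sim["trait_1"], n_randomizations=99, seed=46)
        b = phylo.blomberg_k(yule50, sim["trait_1"], n_randomizations=99, seed=46)
        assert a.p_value == b.p_value and a.K == b.K

    def test_too_few_tips_error(self):
        tree = phylo.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="4 tips"):
            phylo.blomberg_k(tree, {"A": 1.0, "B": 2.0}, n_randomizations=0)


class TestPGLS:
    def test_star_tree_equals_ols_exactly(self):
        star = phylo.read_newick("(A:1,B:1,C:1,D:1,E:1);")
        y = {"A": 1.0, "B": 2.0, "C": 1.5, "D": 3.0, "E": 2.2}
        x = {"A": 0.1, "B": 0.9, "C": 0.4, "D": 1.2, "E": 1.0}
        fit = phylo.pgls(star, y, x)
        labels = sorted(y)
        ref = phylo.ols([y[k] for k in labels], [x[k] for k in labels])
        np.testing.assert_array_equal(fit.coefficients, ref.coefficients)

    def test_identity_response_flagged(self, balanced_tree):
        x = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        fit = phylo.pgls(balanced_tree, x, x)
        assert fit.coefficients[1] == pytest.approx(1.0)
        assert fit.zero_residual

    def test_matches_statsmodels_gls_oracle(self):
        for seed in (3, 4):
            tree = _random_yule(8, seed)
            rng = np.random.default_rng(seed + 100)
            labels, C = phylo.brownian_covariance(tree)
            x = pd.Series(rng.normal(size=8), index=labels)
            y = pd.Series(
                1.0 + 0.7 * x.to_numpy() + rng.normal(scale=0.4, size=8), index=labels
            )
            fit = phylo.pgls(tree, y, x)
            X = np.column_stack([np.ones(8), x.to_numpy()])
            ref = sm.GLS(y.to_numpy(), X, sigma=C).fit()
            np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-10)
            np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-10)
            # ML log-likelihood convention: sigma2 = RSS/n
            assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-10)

    def test_aic_counts_variance_parameter(self, balanced_tree):
        y = {"A": 1.0, "B": 2.4, "C": 0.5, "D": 3.3}
        x = {"A": 0.2, "B": 1.1, "C": 0.3, "D": 1.8}
        fit = phylo.pgls(balanced_tree, y, x)
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.log_likelihood)

    def test_model_select_minimum_aic(self):
        tree = _random_yule(20, 51)
        rng = np.random.default_rng(52)
        labels = sorted(phylo.tip_labels(tree))
        good = pd.Series(rng.normal(size=20), index=labels)
        noise1 = pd.Series(rng.normal(size=20), index=labels)
        noise2 = pd.Series(rng.normal(size=20), index=labels)
        y = 2.0 * good + 0.1 * pd.Series(rng.normal(size=20), index=labels)
        best = phylo.model_select(
            tree, y, pd.DataFrame({"good": good, "n1": noise1, "n2": noise2})
        )
        assert best.predictor == "good"
        assert best.aic_table["aic"].is_monotonic_increasing

    def test_singular_design_errors(self, balanced_tree):
        y = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        x = {"A": 5.0, "B": 5.0, "C": 5.0, "D": 5.0}
        with pytest.raises(ValueError, match="singular"):
            phylo.pgls(balanced_tree, y, x)


class TestPhylANOVA:
    def test_observed_f_matches_textbook_anova(self, yule50):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(61)
        labels = sorted(phylo.tip_labels(yule50))
        x = pd.Series(rng.normal(size=50), index=labels)
        groups = {lab: ("g1" if i < 25 else "g2") for i, lab in enumerate(labels)}
        res = phylo.phyl_anova(yule50, x, groups, n_simulations=49, seed=62)
        ref = f_oneway(x.iloc[:25], x.iloc[25:])
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)

    def test_large_shift_detected(self, yule50):
        sim = phylo.simulate_bm(yule50, rate=0.01, seed=63)["trait_1"]
        labels = sim.index
        groups = {lab: ("g1" if i % 2 == 0 else "g2") for i, lab in enumerate(labels)}
        shifted = sim + pd.Series(
            [10.0 if groups[lab] == "g1" else 0.0 for lab in labels], index=labels
        )
        res = phylo.phyl_anova(yule50, shifted, groups, n_simulations=199, seed=64)
        assert res.p_value <= 0.01

    def test_posthoc_holm_adjusted(self, yule50):
        rng = np.random.default_rng(65)
        labels = sorted(phylo.tip_labels(yule50))
        x = pd.Series(rng.normal(size=50), index=labels)
        groups = {lab: f"g{i % 3}" for i, lab in enumerate(labels)}
        res = phylo.phyl_anova(yule50, x, groups, n_simulations=99, seed=66)
        assert len(res.pairwise) == 3
        assert (res.pairwise["p_holm"] >= res.pairwise["p_sim"] - 1e-12).all()

    def test_small_group_errors(self, balanced_tree):
        x = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        groups = {"A": "g1", "B": "g2", "C": "g2", "D": "g2"}
        with pytest.raises(ValueError, match="fewer than 2"):
            phylo.phyl_anova(balanced_tree, x, groups, n_simulations=9, seed=1)


class TestSimulateBM:
    def test_same_seed_identical(self, yule50):
        a = phylo.simulate_bm(yule50, rate=1.0, seed=71)
        b = phylo.simulate_bm(yule50, rate=1.0, seed=71)
        pd.testing.assert_frame_equal(a, b)

    def test_vanishing_rate_collapses_to_root(self, balanced_tree):
        sim = phylo.simulate_bm(balanced_tree, rate=1e-12, seed=72, root_value=5.0)
        np.testing.assert_allclose(sim.to_numpy(), 5.0, atol=1e-4)

    def test_tip_covariance_matches_shared_branch_lengths(self, balanced_tree):
        sims = phylo.simulate_bm(balanced_tree, rate=2.0, seed=73, n_traits=4000)
        labels, C = phylo.brownian_covariance(balanced_tree)
        emp = np.cov(sims.loc[labels].to_numpy())
        np.testing.assert_allclose(emp, 2.0 * C, atol=0.2)

    def test_nonpositive_rate_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="rate"):
            phylo.simulate_bm(balanced_tree, rate=0.0, seed=1)
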