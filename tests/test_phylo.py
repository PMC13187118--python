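import math

import numpy as np
import pytest
from scipy import stats

from orthotraits.errors import ValidationError
from orthotraits.phylo import (
    blomberg_k,
    bm_loglik,
    fit_bm,
    fit_ou,
    ou_loglik,
    pagel_lambda,
    pgls,
    phylo_anova,
    two_sample_test,
)
from orthotraits.simulate import SynthSpec, simulate_trait
from orthotraits.tree import parse_newick

from .conftest import random_tree, star_tree


class TestBrownianMotion:
    def test_two_tip_closed_form(self):
        tree = parse_newick("(A:1,B:1);")
        fit = fit_bm(tree, {"A": 0.0, "B": 2.0})
        assert fit.params["z0"] == pytest.approx(1.0)
        assert fit.params["sigma2"] == pytest.approx(1.0)
        assert fit.loglik == pytest.approx(-math.log(2 * math.pi) - 1, abs=1e-9)
        assert fit.aic == pytest.approx(4 - 2 * fit.loglik)

    def test_loglik_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(12)
        for seed in range(5):
            tree = random_tree(8, seed=seed)
            C, labels = tree.vcv()
            x = rng.normal(size=8)
            sigma2, z0 = 1.7, 0.3
            oracle = stats.multivariate_normal(mean=np.full(8, z0), cov=sigma2 * C)
            got = bm_loglik(tree, dict(zip(labels, x)), sigma2, z0)
            assert got == pytest.approx(oracle.logpdf(x), abs=1e-8)

    def test_mle_beats_nearby_parameters(self):
        tree = random_tree(16, seed=3)
        x = simulate_trait(tree, SynthSpec(seed=3, n_tips=16))
        fit = fit_bm(tree, x)
        for ds, dz in [(1.1, 0), (0.9, 0), (1, 0.1), (1, -0.1)]:
            worse = bm_loglik(tree, x, fit.params["sigma2"] * ds, fit.params["z0"] + dz)
            assert worse <= fit.loglik + 1e-12

    def test_constant_trait_rejected(self):
        tree = random_tree(8, seed=0)
        with pytest.raises(ValidationError):
            fit_bm(tree, {t: 5.0 for t in tree.tip_labels})

    def test_loglik_invariant_under_tip_reordering(self):
        x = {"A": 0.3, "B": -1.2, "C": 2.0}
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("(C:2,(B:1,A:1):1);")
        assert fit_bm(t1, x).loglik == pytest.approx(fit_bm(t2, x).loglik, abs=1e-12)


class TestOrnsteinUhlenbeck:
    def test_profiled_loglik_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(5)
        tree = random_tree(8, seed=7)
        C, labels = tree.vcv()
        T = float(np.diag(C).max())
        x = rng.normal(size=8)
        alpha = 1.3
        fit = fit_ou(tree, dict(zip(labels, x)))
        V0 = np.exp(-2 * alpha * (T - C)) * (1 - np.exp(-2 * alpha * C)) / (2 * alpha)
        # oracle: profile theta/sigma2 numerically over a grid around the GLS answer
        ll = ou_loglik(tree, dict(zip(labels, x)), alpha)
        best = -np.inf
        for theta in np.linspace(x.min(), x.max(), 60):
            r = x - theta
            quad = r @ np.linalg.solve(V0, r)
            s2 = quad / len(x)
            if s2 <= 0:
                continue
            cand = stats.multivariate_normal(np.full(8, theta), s2 * V0).logpdf(x)
            best = max(best, cand)
        assert ll >= best - 1e-6
        assert fit.loglik >= ll - 1e-9  # ML over alpha at least as good

    def test_alpha_to_zero_recovers_bm(self):
        tree = random_tree(32, seed=4)
        x = simulate_trait(tree, SynthSpec(seed=4, n_tips=32))
        bm = fit_bm(tree, x)
        assert abs(ou_loglik(tree, x, 1e-8) - bm.loglik) < 1e-4

    def test_requires_ultrametric_tree(self):
        tree = parse_newick("((A:1,B:2):1,(C:2,D:1):1);")
        with pytest.raises(ValidationError, match="ultrametric"):
            fit_ou(tree, {"A": 0, "B": 1, "C": 2, "D": 3})

    def test_aic_parameter_counts(self):
        tree = random_tree(16, seed=6)
        x = simulate_trait(tree, SynthSpec(seed=6, n_tips=16))
        bm, ou = fit_bm(tree, x), fit_ou(tree, x)
        assert bm.k == 2 and ou.k == 3
        # OU nests BM, so it wins on AIC exactly when 2*delta-lnL > 2
        assert (ou.aic < bm.aic) == (2 * (ou.loglik - bm.loglik) > 2)


class TestBlombergK:
    def test_star_tree_gives_k_of_one(self):
        tree = star_tree(8)
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = dict(zip(tree.tip_labels, rng.normal(size=8)))
            assert blomberg_k(tree, x, n_perm=0).K == pytest.approx(1.0)

    def test_permutation_p_reproducible_with_seed(self):
        tree = random_tree(16, seed=10)
        x = simulate_trait(tree, SynthSpec(seed=10, n_tips=16))
        p1 = blomberg_k(tree, x, n_perm=199, seed=77).p
        p2 = blomberg_k(tree, x, n_perm=199, seed=77).p
        assert p1 == p2

    def test_signal_detected_on_bm_data(self):
        tree = random_tree(64, seed=11)
        x = simulate_trait(tree, SynthSpec(seed=11, n_tips=64))
        result = blomberg_k(tree, x, n_perm=199, seed=0)
        assert result.p < 0.05

    def test_shuffled_data_weakens_k(self):
        tree = random_tree(64, seed=12)
        rng = np.random.default_rng(12)
        below = 0
        for _ in range(20):
            x = simulate_trait(tree, SynthSpec(seed=12, n_tips=64), rng=rng)
            shuffled = dict(zip(tree.tip_labels, rng.permutation(list(x.values()))))
            if blomberg_k(tree, shuffled, n_perm=0).K < 1:
                below += 1
        assert below >= 19

    def test_too_few_tips_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValidationError):
            blomberg_k(tree, {"A": 0, "B": 1})


class TestPagelLambda:
    def test_lambda_zero_equals_independent_normals(self):
        tree = random_tree(12, seed=13)
        x = simulate_trait(tree, SynthSpec(seed=13, n_tips=12))
        result = pagel_lambda(tree, x)
        C, labels = tree.vcv()
        xv = np.array([x[t] for t in labels])
        # lambda=0: independent normals with variances sigma2 * diag(C)
        d = np.diag(C)
        mu = (xv / d).sum() / (1 / d).sum()
        s2 = (((xv - mu) ** 2) / d).sum() / len(xv)
        oracle0 = stats.multivariate_normal(np.full(len(xv), mu), s2 * np.diag(d)).logpdf(xv)
        assert result.loglik0 == pytest.approx(oracle0, abs=1e-8)

    def test_high_lambda_on_bm_data(self):
        tree = random_tree(64, seed=14)
        x = simulate_trait(tree, SynthSpec(seed=14, n_tips=64))
        result = pagel_lambda(tree, x)
        assert result.lam > 0.8
        assert result.p < 0.05

    def test_low_lambda_on_white_noise(self):
        tree = random_tree(64, seed=15)
        rng = np.random.default_rng(15)
        lams = []
        for _ in range(200):
            x = dict(zip(tree.tip_labels, rng.normal(size=64)))
            lams.append(pagel_lambda(tree, x).lam)
        assert sum(l < 0.2 for l in lams) >= 0.9 * len(lams)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        tree = star_tree(20)
        rng = np.random.default_rng(16)
        pred = dict(zip(tree.tip_labels, rng.integers(0, 2, size=20).astype(float)))
        y = {t: 2.0 + 1.5 * pred[t] + rng.normal() for t in tree.tip_labels}
        result = pgls(tree, y, pred)
        X = np.column_stack([np.ones(20), [pred[t] for t in tree.tip_labels]])
        yv = np.array([y[t] for t in tree.tip_labels])
        beta_ols = np.linalg.lstsq(X, yv, rcond=None)[0]
        assert result.params["estimate"].to_numpy() == pytest.approx(beta_ols, abs=1e-8)

    def test_constant_predictor_rejected(self):
        tree = star_tree(10)
        y = dict(zip(tree.tip_labels, np.arange(10.0)))
        with pytest.raises(ValidationError, match="rank"):
            pgls(tree, y, {t: 1.0 for t in tree.tip_labels})

    def test_group_offset_recovered(self):
        spec = SynthSpec(seed=17, n_tips=64, group_offset=5.0)
        from orthotraits.simulate import gen_tree_and_traits

        tree, traits, groups, _ = gen_tree_and_traits(spec)
        import pandas as pd

        predictors = pd.DataFrame({"diet": pd.Series(groups)})
        result = pgls(tree, traits, predictors)
        est = result.params.at["diet[predator]", "estimate"]
        assert est == pytest.approx(5.0, abs=2.0)
        assert result.params.at["diet[predator]", "p"] < 0.05

    def test_df_equals_n_minus_rank(self):
        tree = star_tree(15)
        rng = np.random.default_rng(18)
        pred = dict(zip(tree.tip_labels, rng.normal(size=15)))
        y = dict(zip(tree.tip_labels, rng.normal(size=15)))
        assert pgls(tree, y, pred).df_resid == 13


class TestPhyloAnova:
    def test_star_tree_matches_parametric_anova(self):
        tree = star_tree(30)
        rng = np.random.default_rng(19)
        labels = ["a"] * 15 + ["b"] * 15
        groups = dict(zip(tree.tip_labels, labels))
        x = dict(zip(tree.tip_labels, rng.normal(size=30) + np.where(np.array(labels) == "a", 0.8, 0.0)))
        result = phylo_anova(tree, x, groups, n_sim=500, seed=5)
        a = [x[t] for t in tree.tip_labels if groups[t] == "a"]
        b = [x[t] for t in tree.tip_labels if groups[t] == "b"]
        parametric = stats.f_oneway(a, b).pvalue
        assert abs(result.p_sim - parametric) < 0.05

    def test_ignoring_phylogeny_is_anticonservative(self):
        # groups aligned with deep clades: BM alone fabricates group effects
        spec = SynthSpec(seed=20, n_tips=32)
        from orthotraits.simulate import gen_tree_and_traits

        deltas = []
        for seed in range(15):
            tree, traits, groups, _ = gen_tree_and_traits(
                SynthSpec(seed=seed + 100, n_tips=32)
            )
            result = phylo_anova(tree, traits, groups, n_sim=200, seed=seed)
            a = [traits[t] for t in tree.tip_labels if groups[t] == "predator"]
            b = [traits[t] for t in tree.tip_labels if groups[t] == "herbivore"]
            parametric = stats.f_oneway(a, b).pvalue
            deltas.append(result.p_sim - parametric)
        assert np.mean(deltas) > 0

    def test_reproducible_with_seed(self):
        tree = random_tree(16, seed=21)
        x = simulate_trait(tree, SynthSpec(seed=21, n_tips=16))
        groups = {t: ("a" if i % 2 else "b") for i, t in enumerate(tree.tip_labels)}
        r1 = phylo_anova(tree, x, groups, n_sim=200, seed=9)
        r2 = phylo_anova(tree, x, groups, n_sim=200, seed=9)
        assert r1.p_sim == r2.p_sim

    def test_degenerate_groups_rejected(self):
        tree = star_tree(6)
        x = {t: 1.0 if i < 3 else 2.0 for i, t in enumerate(tree.tip_labels)}
        groups = {t: ("a" if i < 3 else "b") for i, t in enumerate(tree.tip_labels)}
        with pytest.raises(ValidationError):
            phylo_anova(tree, x, groups, n_sim=10, seed=0)

    def test_small_group_rejected(self):
        tree = star_tree(5)
        x = dict(zip(tree.tip_labels, [1.0, 2.0, 3.0, 4.0, 5.0]))
        groups = dict(zip(tree.tip_labels, ["a", "a", "a", "a", "b"]))
        with pytest.raises(ValidationError, match="fewer than 2"):
            phylo_anova(tree, x, groups, n_sim=10, seed=0)


class TestTwoSampleTest:
    def test_pooled_textbook_example(self):
        result = two_sample_test([1, 2, 3], [4, 5, 6], "pooled")
        assert result.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert result.df == 4

    def test_identical_samples_give_t_zero_p_one(self):
        result = two_sample_test([1, 2, 3], [1, 2, 3], "pooled")
        assert result.statistic == 0 and result.p == pytest.approx(1.0)

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = two_sample_test(a, b, "pooled")
        welch = two_sample_test(a, b, "welch")
        assert welch.statistic == pytest.approx(pooled.statistic)
        assert welch.df == pytest.approx(pooled.df)

    def test_matches_scipy(self):
        rng = np.random.default_rng(22)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=14)
        for variant, scipy_fn in [
            ("pooled", lambda: stats.ttest_ind(a, b)),
            ("welch", lambda: stats.ttest_ind(a, b, equal_var=False)),
            ("wilcoxon", lambda: stats.ranksums(a, b)),
        ]:
            ours = two_sample_test(a, b, variant)
            ref = scipy_fn()
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p == pytest.approx(ref.pvalue)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_test([1.0, 1.0], [1.0, 1.0], "pooled")
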