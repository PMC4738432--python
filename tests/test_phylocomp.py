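import dendropy
import numpy as np
import pytest
import statsmodels.api as sm

from grassflam import phylocomp, synthdata
from oracles import gls_direct, mrca_depth_matrix


def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick", rooting="default-rooted")


class TestPhyloCovariance:
    def test_three_tip_path_arithmetic(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        labels, v = phylocomp.phylo_covariance(tree, 1.0)
        i = {l: k for k, l in enumerate(labels)}
        assert v[i["A"], i["B"]] == pytest.approx(1.0)
        assert v[i["A"], i["C"]] == pytest.approx(0.0)
        assert np.allclose(np.diag(v), 2.0)

    def test_lambda_zero_is_diagonal(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        _, v = phylocomp.phylo_covariance(tree, 0.0)
        assert np.allclose(v, np.diag(np.diag(v)))

    def test_cherry_with_zero_stem_has_zero_covariance(self):
        tree = tree_from_newick("(A:1,B:1):0;")
        _, v = phylocomp.phylo_covariance(tree, 0.7)
        assert v[0, 1] == pytest.approx(0.0)

    def test_lambda_outside_unit_interval_rejected(self):
        tree = tree_from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            phylocomp.phylo_covariance(tree, 1.2)

    def test_matches_brute_force_mrca_oracle(self, tree25):
        labels, v = phylocomp.phylo_covariance(tree25, 1.0)
        labels_o, v_o = mrca_depth_matrix(tree25)
        assert labels == labels_o
        np.testing.assert_allclose(v, v_o, atol=1e-10)

    def test_symmetric_positive_semidefinite(self, tree25):
        _, v = phylocomp.phylo_covariance(tree25, 0.6)
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert np.linalg.eigvalsh(v).min() > -1e-10


class TestPgls:
    def _data(self, tree, rng, beta=(1.0, 0.5), lam=1.0):
        labels, v = phylocomp.phylo_covariance(tree, lam)
        n = len(labels)
        x = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        chol = np.linalg.cholesky(v + 1e-10 * np.eye(n))
        y = x @ np.array(beta) + chol @ rng.standard_normal(n) * 0.5
        return x, y, v

    def test_lambda_zero_equals_ols(self, tree25, rng):
        x, y, v = self._data(tree25, rng)
        fit = phylocomp.pgls_fit(y, x, v, lam=0.0)
        ols = sm.OLS(y, x).fit()
        np.testing.assert_allclose(fit.coef, ols.params, atol=1e-8)

    def test_cholesky_whitening_equals_direct_inverse(self, tree25, rng):
        x, y, v = self._data(tree25, rng)
        fit = phylocomp.pgls_fit(y, x, v, lam=1.0)
        direct = gls_direct(y, x, phylocomp.lambda_transform(v, 1.0))
        np.testing.assert_allclose(fit.coef, direct, atol=1e-9)

    def test_loglik_invariant_to_species_reordering(self, tree25, rng):
        x, y, v = self._data(tree25, rng)
        fit1 = phylocomp.pgls_fit(y, x, v, lam=1.0)
        perm = rng.permutation(len(y))
        fit2 = phylocomp.pgls_fit(y[perm], x[perm], v[np.ix_(perm, perm)], lam=1.0)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)
        np.testing.assert_allclose(np.sort(fit1.coef), np.sort(fit2.coef), atol=1e-8)

    def test_rank_deficient_design_rejected(self, tree25, rng):
        x, y, v = self._data(tree25, rng)
        xx = np.column_stack([x, x[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            phylocomp.pgls_fit(y, xx, v, lam=0.5)


class TestEstimateLambda:
    def test_profile_grid_never_beats_optimizer(self, tree25, rng):
        labels, v = phylocomp.phylo_covariance(tree25, 1.0)
        chol = np.linalg.cholesky(phylocomp.lambda_transform(v, 0.6) + 1e-10 * np.eye(len(labels)))
        y = chol @ rng.standard_normal(len(labels))
        sig = phylocomp.estimate_lambda(y, v)
        x = np.ones((len(labels), 1))
        for lam in np.linspace(0, 1, 11):
            ll = phylocomp.pgls_fit(y, x, v, lam=float(lam)).loglik
            assert ll <= sig.loglik_ml + 1e-6

    def test_star_tree_flagged_flat(self, rng):
        v = np.eye(20)
        y = rng.standard_normal(20)
        sig = phylocomp.estimate_lambda(y, v)
        assert sig.flat_likelihood

    def test_loglik_at_ml_dominates_boundaries(self, tree25, rng):
        _, v = phylocomp.phylo_covariance(tree25, 1.0)
        y = rng.standard_normal(v.shape[0])
        sig = phylocomp.estimate_lambda(y, v)
        assert sig.loglik_ml >= max(sig.loglik_0, sig.loglik_1) - 1e-8
        assert 0.0 <= sig.p_vs_0 <= 1.0 and 0.0 <= sig.p_vs_1 <= 1.0

    def test_rmse_shrinks_with_more_tips(self):
        lam_true = 0.7
        errs = {}
        for n in (25, 100):
            vals = []
            for rep in range(20):
                tree = synthdata.gen_tree(n, seed=1000 * n + rep)
                _, v = phylocomp.phylo_covariance(tree, 1.0)
                rng = np.random.default_rng(rep)
                chol = np.linalg.cholesky(
                    phylocomp.lambda_transform(v, lam_true) + 1e-10 * np.eye(n))
                y = chol @ rng.standard_normal(n)
                vals.append(phylocomp.estimate_lambda(y, v).lambda_ml)
            errs[n] = float(np.sqrt(np.mean((np.array(vals) - lam_true) ** 2)))
        assert errs[100] < errs[25]


class TestHpdAndDiagnostics:
    def test_hpd_contains_mean_for_unimodal_draws(self, rng):
        draws = rng.normal(2.0, 1.0, 5000)
        lo, hi = phylocomp.hpd_interval(draws)
        assert lo < draws.mean() < hi
        # close to the central interval for a symmetric distribution
        assert lo == pytest.approx(2.0 - 1.96, abs=0.15)
        assert hi == pytest.approx(2.0 + 1.96, abs=0.15)

    def test_effective_size_of_iid_draws_near_n(self, rng):
        draws = rng.standard_normal(2000)
        assert phylocomp.effective_size(draws) > 1000

    def test_split_rhat_near_one_for_stationary_chain(self, rng):
        assert phylocomp.split_rhat(rng.standard_normal(2000)) == pytest.approx(1.0, abs=0.05)


class TestBivariateMixedModel:
    def _fit(self, seed, n_per=8, iters=3000):
        tree = synthdata.gen_tree(15, seed=3)
        ssp = synthdata.slope_covariance(0.25, 0.8, 0.09)
        sres = synthdata.slope_covariance(0.04, 0.6, 0.0256)
        x, y, sp, order = synthdata.gen_bivariate_records(tree, n_per, ssp, sres, seed=21)
        _, a = phylocomp.phylo_covariance(tree, 1.0)
        return phylocomp.bivariate_mixed_model(
            x, y, sp, order, a, iterations=iters, burnin=500, thin=3, seed=seed)

    def test_hpds_contain_posterior_means(self):
        post = self._fit(seed=1)
        assert post.b_within_hpd[0] < post.b_within_mean < post.b_within_hpd[1]
        assert post.b_across_hpd[0] < post.b_across_mean < post.b_across_hpd[1]

    def test_chains_agree_within_monte_carlo_error(self):
        p1, p2 = self._fit(seed=1), self._fit(seed=2)
        for a, b in ((p1.b_within_draws, p2.b_within_draws),
                     (p1.b_across_draws, p2.b_across_draws)):
            mcse = np.sqrt(a.var() / phylocomp.effective_size(a)
                           + b.var() / phylocomp.effective_size(b))
            assert abs(a.mean() - b.mean()) <= 2.5 * mcse

    def test_posterior_contracts_with_more_records(self):
        # more individuals per species -> smaller within-slope bias on average
        tree = synthdata.gen_tree(15, seed=9)
        ssp = synthdata.slope_covariance(0.25, 0.8, 0.09)
        sres = synthdata.slope_covariance(0.04, 0.6, 0.0256)
        _, a = phylocomp.phylo_covariance(tree, 1.0)
        bias = {}
        for n_per in (4, 28):
            errs = []
            for rep in range(5):
                x, y, sp, order = synthdata.gen_bivariate_records(
                    tree, n_per, ssp, sres, seed=50 + rep)
                post = phylocomp.bivariate_mixed_model(
                    x, y, sp, order, a, iterations=2000, burnin=400, thin=2,
                    seed=60 + rep)
                errs.append(abs(post.b_within_mean - 0.6))
            bias[n_per] = np.mean(errs)
        assert bias[28] < bias[4]

    def test_independent_traits_cover_zero_slopes(self):
        tree = synthdata.gen_tree(15, seed=5)
        ssp = np.diag([0.25, 0.25])
        sres = np.diag([0.04, 0.04])
        x, y, sp, order = synthdata.gen_bivariate_records(tree, 8, ssp, sres, seed=8)
        _, a = phylocomp.phylo_covariance(tree, 1.0)
        post = phylocomp.bivariate_mixed_model(
            x, y, sp, order, a, iterations=3000, burnin=500, thin=3, seed=4)
        assert post.b_within_hpd[0] < 0 < post.b_within_hpd[1]
        assert post.b_across_hpd[0] < 0 < post.b_across_hpd[1]
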