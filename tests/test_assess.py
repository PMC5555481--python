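"""DIC, plug-in marginal likelihood, cross-validation, model ranking."""

import numpy as np
import pandas as pd
import pytest

import traitnet as tn
from traitnet.assess import (
    FitMetrics,
    MTMModel,
    compute_dic,
    cross_validate,
    make_folds,
    marginal_loglik,
    mcse,
    rank_models,
)
from traitnet.mtm import MCMCSettings

from conftest import block_kinship


class TestComputeDIC:
    def test_constant_deviance_has_zero_penalty(self):
        m = compute_dic(np.full(10, 42.0), 42.0)
        assert m.p_d == 0.0 and m.dic == 42.0

    def test_hand_arithmetic(self):
        m = compute_dic(np.array([10.0, 14.0]), 11.0)
        assert m.p_d == pytest.approx(1.0)
        assert m.dic == pytest.approx(13.0)

    def test_identity_dic_equals_twice_mean_minus_at_mean(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(100, 5, 200)
        at_mean = 95.0
        m = compute_dic(draws, at_mean)
        assert m.dic == pytest.approx(2 * draws.mean() - at_mean)

    def test_nonfinite_draw_reports_index(self):
        draws = np.array([1.0, np.inf, 2.0])
        with pytest.raises(ValueError, match="index 1"):
            compute_dic(draws, 1.0)

    def test_conjugate_gaussian_effective_parameters(self):
        """Known-variance Gaussian mean model: p_D equals the posterior
        shrinkage factor n·v/σ² with v the posterior variance (analytic)."""
        rng = np.random.default_rng(1)
        n, sigma2, tau2 = 40, 1.0, 4.0
        y = rng.normal(0.7, np.sqrt(sigma2), n)
        v = 1.0 / (n / sigma2 + 1.0 / tau2)
        m_post = v * (y.sum() / sigma2)
        thetas = rng.normal(m_post, np.sqrt(v), 200_000)
        dev = np.array(
            [np.sum((y - t) ** 2) / sigma2 + n * np.log(2 * np.pi * sigma2)
             for t in thetas[:50_000]]
        )
        dev_at_mean = np.sum((y - m_post) ** 2) / sigma2 + n * np.log(
            2 * np.pi * sigma2
        )
        m = compute_dic(dev, dev_at_mean)
        expected_p_d = n * v / sigma2
        assert m.p_d == pytest.approx(expected_p_d, rel=0.05)


class TestMarginalLoglik:
    class _Post:
        def __init__(self, mu, G, R):
            self.mu_hat = np.atleast_1d(mu)
            self.G_hat = np.atleast_2d(G)
            self.R_hat = np.atleast_2d(R)

    def _panel(self, values):
        values = np.atleast_2d(values)
        return tn.TraitPanel(
            values=values,
            trait_names=[f"t{k}" for k in range(values.shape[1])],
            genotype_ids=[f"g{i}" for i in range(values.shape[0])],
            family_ids=["F"] * values.shape[0],
        )

    def test_closed_form_univariate(self):
        """d=1, n=2, K=I, σg²=σe²=0.5, y=0: the marginal is two standard
        normals at zero, 2·(−0.9189) = −1.8379."""
        panel = self._panel(np.zeros((2, 1)))
        post = self._Post([0.0], [[0.5]], [[0.5]])
        got = marginal_loglik(post, panel, np.eye(2))
        assert got == pytest.approx(-np.log(2 * np.pi), abs=1e-10)
        assert got == pytest.approx(-1.8379, abs=1e-4)

    def test_invariant_under_genotype_permutation(self, small_kinship, chain3_truth):
        panel = tn.simulate_panel(chain3_truth, small_kinship, seed=40)
        post = self._Post(np.zeros(3), chain3_truth.implied_G, chain3_truth.implied_R)
        base = marginal_loglik(post, panel, small_kinship)
        perm = np.random.default_rng(2).permutation(panel.n)
        panel_p = tn.TraitPanel(
            values=panel.values[perm],
            trait_names=panel.trait_names,
            genotype_ids=[panel.genotype_ids[i] for i in perm],
            family_ids=[panel.family_ids[i] for i in perm],
        )
        K_p = small_kinship[np.ix_(perm, perm)]
        assert marginal_loglik(post, panel_p, K_p) == pytest.approx(base, abs=1e-6)

    def test_true_covariance_beats_diagonal_misspecification(
        self, small_kinship, chain3_truth
    ):
        """Plug-in at the generating G beats a diagonal-G plug-in on most
        panels simulated with strong genomic correlation."""
        wins = 0
        for seed in range(20):
            panel = tn.simulate_panel(chain3_truth, small_kinship, seed=50 + seed)
            good = self._Post(
                np.zeros(3), chain3_truth.implied_G, chain3_truth.implied_R
            )
            bad = self._Post(
                np.zeros(3),
                np.diag(np.diag(chain3_truth.implied_G)),
                chain3_truth.implied_R,
            )
            wins += marginal_loglik(good, panel, small_kinship) > marginal_loglik(
                bad, panel, small_kinship
            )
        assert wins >= 15


class TestFolds:
    def test_partition_is_exact(self):
        folds = make_folds(103, replicates=4, folds=5, seed=1)
        assert folds.shape == (4, 103)
        for r in range(4):
            counts = np.bincount(folds[r], minlength=5)
            assert counts.sum() == 103
            assert counts.min() >= 103 // 5

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(
            make_folds(50, 3, 5, seed=9), make_folds(50, 3, 5, seed=9)
        )

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, 1, 5, seed=0)


class TestCrossValidate:
    def test_fold_assignments_shared_bit_exactly_across_runs(self, small_kinship):
        rng = np.random.default_rng(3)
        n = len(small_kinship)
        panel = tn.TraitPanel(
            values=rng.standard_normal((n, 2)),
            trait_names=["a", "b"],
            genotype_ids=[f"g{i}" for i in range(n)],
            family_ids=["F"] * n,
        )
        mcmc = MCMCSettings(50, 200, 2, seed=0)
        cv1 = cross_validate(panel, small_kinship, [MTMModel(mcmc=mcmc)],
                             replicates=2, folds=4, seed=11)
        cv2 = cross_validate(panel, small_kinship, [MTMModel(mcmc=mcmc)],
                             replicates=2, folds=4, seed=11)
        np.testing.assert_array_equal(cv1.fold_assignments, cv2.fold_assignments)

    def test_identity_kinship_gives_no_predictive_ability(self):
        """With K=I no information flows to held-out genotypes: mean
        predictive ability is within 2 SE of zero."""
        rng = np.random.default_rng(4)
        n, d = 100, 2
        panel = tn.TraitPanel(
            values=rng.standard_normal((n, d)),
            trait_names=["a", "b"],
            genotype_ids=[f"g{i}" for i in range(n)],
            family_ids=["F"] * n,
        )
        mcmc = MCMCSettings(100, 400, 2, seed=1)
        cv = cross_validate(panel, np.eye(n), [MTMModel(mcmc=mcmc)],
                            replicates=2, folds=5, seed=12)
        splits = cv.per_split["MTM"]
        se = splits.std(axis=0, ddof=1) / np.sqrt(splits.shape[0])
        assert np.all(np.abs(splits.mean(axis=0)) < 2 * se + 0.05)

    def test_high_heritability_block_kinship_predicts_well(self):
        """σg²=0.9, σe²=0.1 with family-block kinship: held-out genotypes are
        predicted from relatives, predictive ability > 0.5 for all traits."""
        rng = np.random.default_rng(5)
        K = block_kinship(20, 6, within=0.9)
        n, d = len(K), 2
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        U = L @ rng.standard_normal((n, d)) * np.sqrt(0.9)
        Y = U + rng.standard_normal((n, d)) * np.sqrt(0.1)
        panel = tn.TraitPanel(
            values=Y,
            trait_names=["a", "b"],
            genotype_ids=[f"g{i}" for i in range(n)],
            family_ids=["F"] * n,
        )
        mcmc = MCMCSettings(100, 500, 2, seed=2)
        cv = cross_validate(panel, K, [MTMModel(mcmc=mcmc)],
                            replicates=1, folds=5, seed=13)
        assert np.all(cv.ability_mean.loc["MTM"].to_numpy() > 0.5)


class TestRankModels:
    def _metrics(self, label, dic, p_d, logl):
        return FitMetrics(
            model_label=label, dic=dic, p_d=p_d, mean_deviance=dic - p_d,
            log_marginal=logl,
        )

    def test_reference_vs_itself_has_zero_deltas(self):
        table = rank_models(
            [self._metrics("MTM", 10.0, 2.0, -5.0),
             self._metrics("SEM", 12.0, 1.0, -6.0)]
        )
        assert table.loc["MTM", "delta_dic"] == 0.0
        assert table.loc["MTM", "delta_logL"] == 0.0

    def test_lower_dic_ranks_first_with_positive_delta_for_worse(self):
        table = rank_models(
            [self._metrics("MTM", 10.0, 2.0, -5.0),
             self._metrics("SEM", 12.0, 1.0, -6.0)]
        )
        assert list(table.index) == ["MTM", "SEM"]
        assert table.loc["SEM", "delta_dic"] == pytest.approx(2.0)

    def test_ranking_stable_under_constant_deviance_shift(self):
        a = [self._metrics("MTM", 10.0, 2.0, -5.0),
             self._metrics("SEM", 12.0, 1.0, -6.0)]
        b = [self._metrics("MTM", 110.0, 2.0, -5.0),
             self._metrics("SEM", 112.0, 1.0, -6.0)]
        assert list(rank_models(a).index) == list(rank_models(b).index)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            rank_models([self._metrics("MTM", 1.0, 0.0, 0.0)])


class TestMCSE:
    def test_iid_chain_matches_classic_standard_error(self):
        rng = np.random.default_rng(6)
        draws = rng.standard_normal(3000)
        got = mcse(draws)
        assert got == pytest.approx(draws.std() / np.sqrt(len(draws)), rel=0.5)

    def test_autocorrelated_chain_inflates_error(self):
        rng = np.random.default_rng(7)
        ar = np.empty(5000)
        ar[0] = 0.0
        for t in range(1, 5000):
            ar[t] = 0.95 * ar[t - 1] + rng.standard_normal()
        assert mcse(ar) > ar.std() / np.sqrt(len(ar)) * 2
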