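"""Synthetic panel generator: markers, kinship, trait panels."""

import numpy as np
import pytest

import traitnet as tn
from traitnet.simulate import standardize_panel


class TestSimulateMarkers:
    def test_only_homozygous_codes_and_polymorphic(self, small_markers):
        assert set(np.unique(small_markers.values)) <= {0, 2}
        assert np.all(small_markers.values.min(axis=0) == 0)
        assert np.all(small_markers.values.max(axis=0) == 2)

    def test_same_seed_is_bit_identical(self):
        a = tn.simulate_markers(50, 100, 3, seed=4)
        b = tn.simulate_markers(50, 100, 3, seed=4)
        assert np.array_equal(a.values, b.values)
        assert a.family_ids == b.family_ids

    def test_family_structure_elevates_within_family_similarity(self):
        m = tn.simulate_markers(800, 2000, 10, seed=1)
        K = tn.kinship_from_markers(m)
        fam = np.asarray(m.family_ids)
        same = fam[:, None] == fam[None, :]
        off = ~np.eye(len(fam), dtype=bool)
        within = K[same & off].mean()
        between = K[~same].mean()
        assert within > between

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            tn.simulate_markers(0, 10, 1, seed=0)
        with pytest.raises(ValueError):
            tn.simulate_markers(5, 10, 6, seed=0)

    def test_tiny_panel_with_no_polymorphism_errors(self):
        # 1 line cannot produce a polymorphic marker: every marker is dropped
        with pytest.raises(ValueError, match="monomorphic"):
            tn.simulate_markers(1, 1, 1, seed=0)


class TestKinship:
    def test_identical_lines_match_perfectly(self):
        m = tn.MarkerMatrix(
            values=np.array([[0, 2, 0, 2], [0, 2, 0, 2]]),
            line_ids=["a", "b"],
            family_ids=["F1", "F1"],
        )
        K = tn.kinship_from_markers(m)
        assert K[0, 1] == 1.0

    def test_half_matching_lines(self):
        m = tn.MarkerMatrix(
            values=np.array([[0, 0, 2, 2], [0, 2, 2, 0]]),
            line_ids=["a", "b"],
            family_ids=["F1", "F1"],
        )
        assert tn.kinship_from_markers(m)[0, 1] == 0.5

    def test_matches_brute_force_double_loop(self):
        m = tn.simulate_markers(100, 500, 4, seed=3)
        K = tn.kinship_from_markers(m)
        X = m.values
        n = X.shape[0]
        expected = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                expected[i, j] = np.mean(X[i] == X[j])
        np.testing.assert_allclose(K, expected, atol=1e-12)
        assert np.all(np.diag(K) == 1.0)
        assert K.min() >= 0.0 and K.max() <= 1.0

    def test_single_marker_rejected(self):
        m = tn.MarkerMatrix(
            values=np.array([[0], [2]]), line_ids=["a", "b"], family_ids=["F", "F"]
        )
        with pytest.raises(ValueError):
            tn.kinship_from_markers(m)


class TestSyntheticTruth:
    def test_zero_structures_imply_diagonal_covariances(self):
        t = tn.SyntheticTruth(
            lambda_u=np.zeros((2, 2)),
            lambda_e=np.zeros((2, 2)),
            psi_u=np.array([1.0, 2.0]),
            psi_e=np.array([3.0, 4.0]),
            mu=np.zeros(2),
        )
        np.testing.assert_allclose(t.implied_G, np.diag([1.0, 2.0]))
        np.testing.assert_allclose(t.implied_R, np.diag([3.0, 4.0]))

    def test_fully_recursive_implied_covariance(self, chain3_truth):
        expected = np.array([[1.0, 1, 2], [1, 2, 3], [2, 3, 6]])
        np.testing.assert_allclose(chain3_truth.implied_G, expected)

    def test_implied_covariances_positive_definite(self, sparse5_truth):
        for cov in (sparse5_truth.implied_G, sparse5_truth.implied_R):
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_upper_triangular_structure_rejected(self):
        lam = np.zeros((2, 2))
        lam[0, 1] = 0.5
        with pytest.raises(ValueError, match="lower triangular"):
            tn.SyntheticTruth(
                lambda_u=lam,
                lambda_e=np.zeros((2, 2)),
                psi_u=np.ones(2),
                psi_e=np.ones(2),
                mu=np.zeros(2),
            )

    def test_yaml_round_trip(self, tmp_path, sparse5_truth):
        path = tmp_path / "truth.yaml"
        sparse5_truth.to_yaml(path)
        back = tn.SyntheticTruth.from_yaml(path)
        np.testing.assert_allclose(back.lambda_u, sparse5_truth.lambda_u)
        np.testing.assert_allclose(back.psi_e, sparse5_truth.psi_e)


class TestSimulatePanel:
    def test_independent_components_give_additive_variance(self):
        d = 2
        t = tn.SyntheticTruth(
            lambda_u=np.zeros((d, d)),
            lambda_e=np.zeros((d, d)),
            psi_u=np.ones(d),
            psi_e=np.ones(d),
            mu=np.zeros(d),
        )
        n = 5000
        panel = tn.simulate_panel(t, np.eye(n), seed=2)
        var = panel.values.var(axis=0, ddof=1)
        # Var(y) = 2 for each trait; SE of a variance estimate ~ sqrt(2/n)*var
        se = 2.0 * np.sqrt(2.0 / n)
        assert np.all(np.abs(var - 2.0) < 3 * se)

    def test_genomic_component_matches_implied_covariance(self, chain3_truth):
        n = 5000
        panel = tn.simulate_panel(chain3_truth, np.eye(n), seed=8)
        S = np.cov(panel.true_u, rowvar=False)
        G = chain3_truth.implied_G
        se = np.sqrt(
            (np.outer(np.diag(G), np.diag(G)) + G**2) / n
        )  # Gaussian cov-estimate SE
        assert np.all(np.abs(S - G) < 4 * se)

    def test_identity_kinship_gives_uncorrelated_genotypes(self, chain3_truth):
        panel = tn.simulate_panel(chain3_truth, np.eye(1000), seed=3)
        u = panel.true_u[:, 0]
        # adjacent-genotype correlation should vanish
        r = np.corrcoef(u[:-1], u[1:])[0, 1]
        assert abs(r) < 0.1

    def test_same_seed_is_bit_identical(self, chain3_truth, small_kinship):
        a = tn.simulate_panel(chain3_truth, small_kinship, seed=5)
        b = tn.simulate_panel(chain3_truth, small_kinship, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_kinship_size_mismatch_rejected(self, chain3_truth):
        with pytest.raises(ValueError):
            tn.simulate_panel(chain3_truth, np.eye(10), n=20, seed=0)

    def test_csv_round_trip(self, tmp_path, chain3_truth, small_kinship):
        panel = tn.simulate_panel(chain3_truth, small_kinship, seed=5)
        path = tmp_path / "panel.csv"
        panel.to_csv(path)
        back = tn.TraitPanel.from_csv(path)
        np.testing.assert_allclose(back.values, panel.values, atol=1e-12)
        assert back.trait_names == panel.trait_names


class TestStandardization:
    def make_panel(self):
        rng = np.random.default_rng(0)
        values = rng.normal(5.0, 2.0, size=(60, 3))
        fams = ["F1"] * 30 + ["F2"] * 30
        return tn.TraitPanel(
            values=values,
            trait_names=["a", "b", "c"],
            genotype_ids=[f"g{i}" for i in range(60)],
            family_ids=fams,
        )

    def test_family_means_zero_and_unit_variance(self):
        std = standardize_panel(self.make_panel())
        fam = np.asarray(std.family_ids)
        for f in np.unique(fam):
            np.testing.assert_allclose(
                std.values[fam == f].mean(axis=0), 0.0, atol=1e-10
            )
        np.testing.assert_allclose(std.values.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_idempotent(self):
        once = standardize_panel(self.make_panel())
        twice = standardize_panel(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_constant_trait_rejected(self):
        p = self.make_panel()
        p.values[:, 1] = 3.0
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_panel(p)
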