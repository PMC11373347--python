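"""Hierarchical decomposition: cluster PCA, fit, reconstruction, ledger."""

import numpy as np
import pytest

import hcsim as H
from hcsim.hcd import cluster_pca
from hcsim.matrix import ValidationError


def _rank1_blocks(n=80, sizes=(5, 6, 7), seed=0):
    """Noiseless data: each block an exact rank-1 multiple of one factor."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for b, size in enumerate(sizes, start=1):
        f = rng.standard_normal(n)
        for j in range(size):
            cols.append((j + 1.0) * f)
            labels.append(b)
    return H.matrix_from_values(np.column_stack(cols)), H.Partition(
        labels=np.array(labels)
    )


class TestClusterPCA:
    def test_single_member_cluster_is_the_centered_variable(self):
        x = np.random.default_rng(0).standard_normal((20, 1))
        center, scores, loadings, _ = cluster_pca(x, k=5)
        np.testing.assert_allclose(scores @ loadings, x - center, atol=1e-12)
        assert loadings.shape == (1, 1)
        assert loadings[0, 0] == pytest.approx(1.0)

    def test_perfectly_anticorrelated_pair_is_rank_one(self):
        x = np.random.default_rng(1).standard_normal(25)
        Xc = np.column_stack([x, -x])
        center, scores, loadings, pc_var = cluster_pca(Xc, k=1)
        recon = center + scores @ loadings
        np.testing.assert_allclose(recon, Xc, atol=1e-10)
        assert pc_var[0] == pytest.approx(2 * x.var(ddof=1), rel=1e-10)

    def test_explained_variance_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        Xc = rng.standard_normal((30, 6)) @ rng.standard_normal((6, 6))
        _, scores, _, pc_var = cluster_pca(Xc, k=3)
        eig = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))[::-1]
        np.testing.assert_allclose(
            pc_var / eig.sum(), eig[:3] / eig.sum(), atol=1e-10
        )

    def test_scores_are_orthogonal_and_variances_non_increasing(self):
        Xc = np.random.default_rng(3).standard_normal((40, 8))
        _, scores, _, pc_var = cluster_pca(Xc, k=5)
        G = scores.T @ scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
        assert np.all(np.diff(pc_var) <= 1e-12)

    def test_sign_convention_largest_loading_positive(self):
        Xc = np.random.default_rng(4).standard_normal((30, 5))
        _, _, loadings, _ = cluster_pca(Xc, k=3)
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_cluster_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cluster_pca(np.ones((10, 3)), k=1)


class TestHCRFit:
    def test_pure_rank_one_blocks_fully_explained_at_level_one(self):
        X, p = _rank1_blocks()
        model = H.hcr_fit(X, f_E=0.99, k=1, g_max=1, seed=0, initial_partition=p)
        assert H.variance_explained(model) == pytest.approx(1.0, abs=1e-8)
        assert model.n_levels == 1

    def test_planted_two_level_recovery(self, planted, fitted_model):
        X, truth = planted
        model = fitted_model
        assert abs(H.variance_explained(model) - 0.7) <= 0.05
        assert H.ground_truth_ari(model.levels[0].partition, truth.level1) >= 0.9
        assert H.ground_truth_ari(model.levels[1].partition, truth.level2) >= 0.9

    def test_insufficient_noiseless_variance_raises(self):
        # construct a partition whose noise subset holds 40% of total variance
        rng = np.random.default_rng(0)
        X = H.matrix_from_values(rng.standard_normal((50, 10)))
        labels = np.array([1] * 6 + [0] * 4)  # equal unit variances: V_C0 = 0.4 V_X
        with pytest.raises(H.InsufficientVarianceError) as err:
            H.hcr_fit(X, f_E=0.9, k=2, g_max=1, seed=0,
                      initial_partition=H.Partition(labels=labels))
        assert err.value.required > err.value.available

    def test_partitions_are_nested(self, fitted_model):
        model = fitted_model
        l1, l2 = model.levels[0].partition, model.levels[1].partition
        for c in l2.cluster_labels():
            parents = set(l1.labels[l2.members(c)])
            assert len(parents) == 1

    def test_variance_explained_monotone_in_k_and_levels(self, planted):
        X, _ = planted
        ve = [
            H.variance_explained(H.hcr_fit(X, f_E=0.9, k=k, g_max=1, seed=1))
            for k in (1, 2, 3)
        ]
        assert ve[0] <= ve[1] + 1e-12 and ve[1] <= ve[2] + 1e-12
        m2 = H.hcr_fit(X, f_E=0.9, k=1, g_max=2, seed=1)
        assert [lv.v_explained_after for lv in m2.levels] == sorted(
            lv.v_explained_after for lv in m2.levels
        )


class TestReconstruct:
    def test_full_order_reconstruction_is_exact(self):
        X, p = _rank1_blocks(sizes=(4, 5))
        model = H.hcr_fit(
            X, f_E=1.0, k=X.n_variables, g_max=1, seed=0, initial_partition=p
        )
        np.testing.assert_allclose(H.reconstruct(model), X.values, atol=1e-8)

    def test_truncated_reconstruction_explains_less(self, planted, fitted_model):
        X, _ = planted
        v1 = H.reconstruct(fitted_model, up_to_level=1).var(axis=0, ddof=1).sum()
        v2 = H.reconstruct(fitted_model).var(axis=0, ddof=1).sum()
        assert v1 < v2

    def test_level_beyond_model_depth_rejected(self, fitted_model):
        with pytest.raises(ValueError, match="up_to_level"):
            H.reconstruct(fitted_model, up_to_level=5)

    def test_variance_conservation_ledger(self, planted, fitted_model):
        """Per variable: Var(X) = Var(X^R) + Var(E), to 1e-8 relative."""
        X, _ = planted
        XR = H.reconstruct(fitted_model)
        recon_var = XR.var(axis=0, ddof=1)
        total = recon_var + fitted_model.residual_variances
        np.testing.assert_allclose(
            total, fitted_model.original_variances, rtol=1e-8
        )

    def test_eq1_locality_all_pcs_reproduce_cluster_variance(self, small_model):
        """Within a cluster, sum of all PC variances equals the cluster's
        input variance when every PC is retained."""
        X, _ = small_model
        labels = np.repeat([1, 1, 2, 2], 5)
        p = H.Partition(labels=labels)
        model = H.fit_decomposition(X, [p], k=X.n_samples)
        for cp in model.levels[0].clusters:
            v_cluster = X.values[:, cp.member_indices].var(axis=0, ddof=1).sum()
            assert cp.pc_variances.sum() == pytest.approx(v_cluster, rel=1e-8)

    def test_permutation_equivariance(self, planted):
        X, truth = planted
        rng = np.random.default_rng(11)
        perm = rng.permutation(X.n_variables)
        Xp = H.matrix_from_values(
            X.values[:, perm], [X.variable_ids[i] for i in perm]
        )
        p1 = H.Partition(labels=truth.level1.labels)
        p1p = H.Partition(labels=truth.level1.labels[perm])
        m = H.hcr_fit(X, f_E=0.9, k=1, g_max=1, seed=1, initial_partition=p1)
        mp = H.hcr_fit(Xp, f_E=0.9, k=1, g_max=1, seed=1, initial_partition=p1p)
        np.testing.assert_allclose(
            H.reconstruct(mp), H.reconstruct(m)[:, perm], atol=1e-8
        )


class TestVarianceMatchingNoise:
    def test_fully_explained_variable_unchanged(self):
        X, p = _rank1_blocks(sizes=(4, 4))
        model = H.hcr_fit(X, f_E=1.0, k=4, g_max=1, seed=0, initial_partition=p)
        XR = H.reconstruct(model)
        out = H.add_variance_matching_noise(XR, model, seed=5)
        np.testing.assert_array_equal(out, XR)

    def test_realized_variance_matches_original(self):
        rng = np.random.default_rng(8)
        n = 10000
        f = rng.standard_normal(n)
        cols = [np.sqrt(0.5) * f + np.sqrt(0.5) * rng.standard_normal(n)
                for _ in range(6)]
        X = H.matrix_from_values(np.column_stack(cols))
        p = H.Partition(labels=np.ones(6, dtype=int))
        model = H.hcr_fit(X, f_E=0.9, k=1, g_max=1, seed=0, initial_partition=p)
        out = H.add_variance_matching_noise(H.reconstruct(model), model, seed=2)
        np.testing.assert_allclose(
            out.var(axis=0, ddof=1), model.original_variances, rtol=0.05
        )

    def test_seed_determinism(self, planted, fitted_model):
        XR = H.reconstruct(fitted_model)
        a = H.add_variance_matching_noise(XR, fitted_model, seed=3)
        b = H.add_variance_matching_noise(XR, fitted_model, seed=3)
        c = H.add_variance_matching_noise(XR, fitted_model, seed=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestAccounting:
    def test_variance_explained_equals_ledger_identity(self, fitted_model):
        ve = H.variance_explained(fitted_model)
        ident = 1.0 - (
            fitted_model.residual_variances.sum()
            / fitted_model.original_variances.sum()
        )
        assert ve == pytest.approx(ident, abs=1e-10)

    def test_single_cluster_pc_count(self):
        X, _ = _rank1_blocks(sizes=(6,))
        p = H.Partition(labels=np.ones(6, dtype=int))
        model = H.hcr_fit(X, f_E=1.0, k=2, g_max=1, seed=0, initial_partition=p)
        counts = H.pc_count_summary(model)
        assert counts == {"total_pcs": 2, "max_pcs_per_variable": 2}

    def test_worked_example_hierarchy_pc_accounting(self, planted):
        """k=5 over 3 parent + 11 child clusters: 70 PCs, at most 10 per
        variable (5 + 5 across the two levels)."""
        X, truth = planted
        model = H.fit_decomposition(X, [truth.level1, truth.level2], k=5)
        counts = H.pc_count_summary(model)
        assert counts["total_pcs"] == 70
        assert counts["max_pcs_per_variable"] == 10
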