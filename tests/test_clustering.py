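"""Adaptive (MCL + noise rule) and separator clustering stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hcsim as H
from hcsim.clustering import SplitCandidate, _relabel_contiguous
from hcsim.matrix import ValidationError


def _block_similarity(sizes, within, between, rng=None):
    n = sum(sizes)
    S = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        S[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(S, 1.0)
    return H.SimilarityMatrix(values=S)


class TestCorrelationSimilarity:
    def test_affine_related_variables_have_unit_similarity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2 * x + 3, rng.standard_normal(30)])
        S = H.correlation_similarity(X)
        assert S.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_centered_vectors_have_zero_similarity(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        S = H.correlation_similarity(np.column_stack([x, y]))
        assert S.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_two_pass_covariance(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10, 6))
        S = H.correlation_similarity(X)
        for i in range(6):
            for j in range(6):
                xi, xj = X[:, i], X[:, j]
                cov = np.sum((xi - xi.mean()) * (xj - xj.mean())) / 9
                r = cov / np.sqrt(xi.var(ddof=1) * xj.var(ddof=1))
                assert S.values[i, j] == pytest.approx(
                    min(r * r, 1.0), abs=1e-12
                )

    def test_zero_variance_variable_is_named(self):
        X = H.matrix_from_values(
            np.column_stack([np.ones(5), np.arange(5.0)]), ["flat", "ok"]
        )
        with pytest.raises(ValidationError, match="flat"):
            H.correlation_similarity(X)


class TestMCL:
    def test_disconnected_blocks_never_merge(self):
        S = _block_similarity([5, 5], within=0.9, between=0.0)
        p = H.mcl(S)
        assert p.n_clusters == 2
        assert len(set(p.labels[:5])) == 1 and len(set(p.labels[5:])) == 1
        assert set(p.labels[:5]) != set(p.labels[5:])

    def test_identity_similarity_gives_singletons(self):
        S = H.SimilarityMatrix(values=np.eye(8), diagonal_policy="one")
        p = H.mcl(S)
        assert p.n_clusters == 8

    def test_planted_three_blocks_recovered(self):
        S = _block_similarity([6, 8, 7], within=0.8, between=0.05)
        p = H.mcl(S, inflation=2.0)
        truth = H.Partition(labels=np.repeat([1, 2, 3], [6, 8, 7]))
        assert H.ground_truth_ari(p, truth) == pytest.approx(1.0)

    def test_permutation_of_variables_permutes_labels(self):
        S = _block_similarity([6, 8, 7], within=0.8, between=0.05)
        rng = np.random.default_rng(5)
        perm = rng.permutation(21)
        Sp = H.SimilarityMatrix(values=S.values[np.ix_(perm, perm)])
        p = H.mcl(S)
        pp = H.mcl(Sp)
        assert H.ground_truth_ari(
            H.Partition(labels=pp.labels),
            H.Partition(labels=p.labels[perm]),
        ) == pytest.approx(1.0)

    def test_asymmetric_similarity_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            H.SimilarityMatrix(values=bad)


class TestDesignateNoise:
    @staticmethod
    def _partition(sizes):
        return H.Partition(labels=np.repeat(np.arange(1, len(sizes) + 1), sizes))

    def test_tiny_cluster_below_min_size_becomes_noise(self):
        p = H.designate_noise(self._partition([50, 40, 2]), min_size=3)
        assert p.n_clusters == 2
        assert (p.labels == 0).sum() == 2

    def test_comparable_clusters_renumbered_by_size(self):
        p = H.designate_noise(
            self._partition([50, 40, 45]), min_size=3, rel_frac=0.1
        )
        assert p.n_clusters == 3
        assert (p.labels == 0).sum() == 0
        sizes = p.sizes()
        assert [sizes[c] for c in (1, 2, 3)] == [50, 45, 40]

    def test_relative_fraction_uses_size_experienced_by_variables(self):
        p = H.designate_noise(
            self._partition([100, 9, 8]), min_size=3, rel_frac=0.2
        )
        assert p.n_clusters == 1
        assert (p.labels == 0).sum() == 17

    def test_everything_noise_is_an_error(self):
        with pytest.raises(ValidationError, match="threshold"):
            H.designate_noise(self._partition([2, 2]), min_size=5)


class TestNormalizedEntropy:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([2, 2], 1.0),
            ([5, 5, 5], 1.0),
            # -(0.75 ln 0.75 + 0.25 ln 0.25) / ln 2
            ([3, 1], 0.8112781244591328),
        ],
    )
    def test_known_values(self, sizes, expected):
        assert H.normalized_entropy(sizes) == pytest.approx(expected, abs=1e-10)

    def test_rejects_trivial_or_empty_splits(self):
        with pytest.raises(ValueError):
            H.normalized_entropy([4])
        with pytest.raises(ValueError):
            H.normalized_entropy([3, 0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=8))
    def test_bounded_and_maximal_only_on_even_splits(self, sizes):
        h = H.normalized_entropy(sizes)
        assert 0.0 <= h <= 1.0 + 1e-12
        if len(set(sizes)) == 1:
            assert h == pytest.approx(1.0)
        else:
            assert h < 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(min_value=2, max_value=30), min_size=2, max_size=6),
        st.data(),
    )
    def test_moving_a_member_to_a_larger_cluster_decreases_entropy(self, sizes, data):
        i = data.draw(st.integers(0, len(sizes) - 1))
        j = data.draw(st.integers(0, len(sizes) - 1))
        if i == j or sizes[j] < sizes[i]:
            return
        moved = list(sizes)
        moved[i] -= 1
        moved[j] += 1
        assert H.normalized_entropy(moved) < H.normalized_entropy(sizes) + 1e-12


class TestSeparatorSplit:
    def test_two_perfect_pairs_split_into_pairs(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        E = np.column_stack([a, -a, b, 2 * b])
        p = H.separator_split(E, n_range=(2, 3))
        assert p.n_clusters == 2
        assert p.labels[0] == p.labels[1] and p.labels[2] == p.labels[3]
        assert p.labels[0] != p.labels[2]

    def test_all_mutually_correlated_gives_even_cut_at_smallest_ng(self):
        x = np.random.default_rng(1).standard_normal(30)
        E = np.column_stack([x, 2 * x, -x, 3 * x])
        p = H.separator_split(E, n_range=(2, 4))
        sizes = sorted(p.sizes().values())
        assert p.n_clusters == 2 and sizes == [2, 2]

    def test_three_planted_subfactors_recovered(self):
        rng = np.random.default_rng(7)
        factors = rng.standard_normal((200, 3))
        cols, truth = [], []
        for f_idx in range(3):
            for _ in range(4):
                cols.append(
                    np.sqrt(0.8) * factors[:, f_idx]
                    + np.sqrt(0.2) * rng.standard_normal(200)
                )
                truth.append(f_idx + 1)
        p = H.separator_split(np.column_stack(cols), n_range=(2, 7))
        assert H.ground_truth_ari(p, H.Partition(labels=np.array(truth))) == pytest.approx(1.0)

    def test_cluster_smaller_than_min_cut_returns_trivial_flagged(self):
        E = np.random.default_rng(0).standard_normal((10, 1))
        p = H.separator_split(E, n_range=(2, 7))
        assert p.n_clusters == 1 and not p.converged

    def test_zero_variance_member_joins_most_correlated_peer(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        E = np.column_stack([a, a + 0.1 * rng.standard_normal(50), b,
                             b + 0.1 * rng.standard_normal(50), np.zeros(50)])
        orig = E.copy()
        orig[:, 4] = b + 0.05 * rng.standard_normal(50)  # original data correlates with b
        p = H.separator_split(E, n_range=(2, 3), original=orig)
        assert p.labels[4] == p.labels[2]


def test_relabel_contiguous_orders_by_first_appearance():
    out = _relabel_contiguous(np.array([7, 7, 3, 7, 3, 9]))
    np.testing.assert_array_equal(out, [1, 1, 2, 1, 2, 3])
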