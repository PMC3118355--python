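import numpy as np
import pytest

from kdnorm import (
    LOG2,
    ExpressionMatrix,
    MAProjection,
    kdq_normalize,
    kdq_score,
    quantile_normalize,
    quantile_normalize_values,
    select_invariant_set,
)


class TestSelectInvariantSet:
    def _ma(self, a, m):
        return MAProjection(A=a, M=m, target_array_id="x")

    def test_proportion_one_selects_everything(self, rng):
        ma = self._ma(rng.normal(8, 2, 30), rng.normal(0, 0.3, 30))
        inv = select_invariant_set(ma, 1.0)
        np.testing.assert_array_equal(inv.indices, np.arange(30))

    @pytest.mark.parametrize("prop,expected", [(0.5, 500), (0.85, 850)])
    def test_selected_count_is_ceiling(self, rng, prop, expected):
        ma = self._ma(rng.normal(8, 2, 1000), rng.normal(0, 0.3, 1000))
        assert len(select_invariant_set(ma, prop).indices) == expected

    def test_dense_cluster_preferred(self, rng):
        # 900 dense null points, 100 sparse points >> 10 bandwidths away in M
        a = rng.normal(8, 1.0, 1000)
        m = np.concatenate([rng.normal(0, 0.05, 900), rng.normal(30.0, 0.05, 100)])
        inv = select_invariant_set(self._ma(a, m), 0.5)
        assert (inv.indices < 900).mean() >= 0.95

    def test_bad_proportion_rejected(self, rng):
        ma = self._ma(rng.normal(size=10), rng.normal(size=10))
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="proportion"):
                select_invariant_set(ma, p)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        out = quantile_normalize_values(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_permuted_columns_share_values(self, rng):
        base = rng.normal(size=20)
        cols = np.column_stack([rng.permutation(base) for _ in range(4)])
        out = quantile_normalize_values(cols)
        for j in range(4):
            np.testing.assert_allclose(np.sort(out[:, j]), np.sort(base), atol=1e-12)

    def test_sorted_columns_identical_after(self, rng):
        v = rng.normal(size=(50, 4))
        out = quantile_normalize_values(v)
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_get_mean_of_rank_averages(self):
        # first column has a tie occupying ranks 0 and 1
        v = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize_values(v)
        rank_means = np.array([(1.0 + 10.0) / 2, (1.0 + 20.0) / 2, (5.0 + 30.0) / 2])
        tied = 0.5 * (rank_means[0] + rank_means[1])
        np.testing.assert_allclose(out[:, 0], [tied, tied, rank_means[2]])


class TestKdqScore:
    def test_interpolation_midpoint(self):
        assert kdq_score(2.0, [1.0, 3.0], [10.0, 30.0]) == pytest.approx(20.0)

    def test_extrapolation_shift_rule(self):
        # top-2 boundary means x_a = 9, y_a = 19; score(12) = 19 + (12 - 9)
        assert kdq_score(12.0, [8.0, 10.0], [18.0, 20.0], m_boundary=2) == pytest.approx(22.0)

    def test_low_end_mirrored_rule(self):
        # bottom-2 means x_b = 9, y_b = 19; score(5) = 19 + (5 - 9) = 15
        assert kdq_score(5.0, [8.0, 10.0], [18.0, 20.0], m_boundary=2) == pytest.approx(15.0)

    def test_invariant_points_map_exactly(self):
        x = np.array([1.0, 2.5, 4.0, 7.0])
        y = np.array([2.0, 3.0, 3.5, 9.0])
        np.testing.assert_array_equal(kdq_score(x, x, y), y)

    def test_monotone_when_anchor_monotone(self, rng):
        inv_x = np.sort(rng.uniform(0, 10, 50))
        inv_x += np.arange(50) * 1e-9  # ensure strictly increasing
        inv_y = np.sort(rng.uniform(0, 10, 50))
        q = np.sort(rng.uniform(-5, 15, 200))
        s = kdq_score(q, inv_x, inv_y, m_boundary=10)
        assert (np.diff(s) >= -1e-12).all()

    def test_too_few_invariant_points_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            kdq_score(1.0, [1.0], [2.0])


class TestKdqNormalize:
    def test_identical_arrays_are_fixed_point(self, rng):
        col = rng.normal(8, 2, 80)
        m = ExpressionMatrix(
            values=np.column_stack([col] * 3),
            probe_ids=[f"p{i}" for i in range(80)],
            array_ids=["a", "b", "c"],
            scale=LOG2,
        )
        out = kdq_normalize(m, proportion=0.5)
        np.testing.assert_allclose(out.values, m.values, rtol=0, atol=1e-12)

    def test_proportion_one_equals_plain_quantile(self, small_log2_matrix):
        with pytest.warns(UserWarning, match="0.85"):
            out = kdq_normalize(small_log2_matrix, proportion=1.0)
        expected = quantile_normalize(small_log2_matrix)
        np.testing.assert_array_equal(out.values, expected.values)

    def test_invariant_probes_get_quantile_values(self, small_log2_matrix):
        """Probes inside the invariant set land exactly on their
        quantile-normalized values (interpolation endpoints)."""
        from kdnorm.core import common_reference
        from kdnorm.kdq import _point_densities
        from math import ceil

        m = small_log2_matrix
        out = kdq_normalize(m, proportion=0.5)
        # rebuild the pooled selection independently
        ref = common_reference(m)
        score = np.zeros(m.n_probes)
        for j, aid in enumerate(m.array_ids):
            ma = MAProjection(A=ref, M=m.values[:, j] - ref, target_array_id=aid)
            score += _point_densities(ma, None)
        keep = np.sort(np.argsort(-score, kind="stable")[: ceil(0.5 * m.n_probes)])
        qsub = quantile_normalize_values(m.values[keep, :])
        np.testing.assert_allclose(out.values[keep, :], qsub, atol=1e-12)

    def test_small_invariant_set_rejected(self, rng):
        m = ExpressionMatrix(
            values=rng.normal(8, 2, size=(300, 3)),
            probe_ids=[f"p{i}" for i in range(300)],
            array_ids=["a", "b", "c"],
            scale=LOG2,
        )
        with pytest.raises(ValueError, match="increase the proportion"):
            kdq_normalize(m, proportion=0.003)

    def test_intersection_mode_runs_and_is_conservative(self, small_log2_matrix):
        out = kdq_normalize(small_log2_matrix, proportion=0.8, selection="intersection")
        assert out.values.shape == small_log2_matrix.values.shape
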