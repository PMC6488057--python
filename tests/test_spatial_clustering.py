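import numpy as np
import pytest

from gaitpet.spatial_clustering import (
    classify_hot,
    cluster_index,
    compute_cluster_index,
    count_hot_neighbors,
    permutation_null,
    scatter_flags,
)


def brute_force_nhn(roi, hot):
    """All-pairs adjacency oracle: NHN via explicit L1-distance comparisons."""
    roi_idx = np.argwhere(roi)
    hot_idx = np.argwhere(hot)
    nhn = np.zeros(roi.shape, dtype=int)
    if len(hot_idx):
        diff = np.abs(roi_idx[:, None, :] - hot_idx[None, :, :]).sum(axis=2)
        nhn[tuple(roi_idx.T)] = (diff == 1).sum(axis=1)
    return nhn


def two_by_two_by_ten():
    """The worked 40-voxel example: hot voxels at (0,0,4) and (0,0,5)."""
    roi = np.ones((2, 2, 10), dtype=bool)
    values = np.zeros((2, 2, 10))
    values[0, 0, 4] = values[0, 0, 5] = 10.0
    return roi, values


class TestClassifyHot:
    def test_twenty_distinct_values_single_hot_maximum(self):
        values = np.arange(20.0)
        lab = classify_hot(values)
        assert lab.m == 1 and lab.n == 19
        assert np.flatnonzero(lab.hot_flags).tolist() == [19]

    def test_all_equal_ties_broken_by_lowest_index(self):
        lab = classify_hot(np.ones(40))
        assert lab.m == 2
        assert np.flatnonzero(lab.hot_flags).tolist() == [0, 1]
        assert lab.ties_broken

    def test_rank_invariance_under_increasing_transform(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, 1.0, 200)
        a = classify_hot(values)
        b = classify_hot(np.exp(values) + 3.0)
        np.testing.assert_array_equal(a.hot_flags, b.hot_flags)

    @pytest.mark.parametrize("n,expected_m", [(20, 1), (40, 2), (100, 5), (9, 1), (30, 2)])
    def test_half_up_hot_count(self, n, expected_m):
        lab = classify_hot(np.arange(float(n)))
        assert lab.m == expected_m

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            classify_hot([])

    def test_correction_factor_19_at_default_fraction(self):
        assert classify_hot(np.arange(40.0)).correction_factor == pytest.approx(19.0)


class TestCountHotNeighbors:
    def test_isolated_hot_voxel_has_zero_nhn(self):
        roi = np.ones((3, 3, 3), dtype=bool)
        hot = np.zeros_like(roi)
        hot[1, 1, 1] = True
        nhn = count_hot_neighbors(hot, roi)
        assert nhn[1, 1, 1] == 0
        assert nhn[0, 1, 1] == 1  # cold face-neighbour sees one hot voxel

    def test_fully_hot_cube_centre_saturates_at_six(self):
        roi = np.ones((3, 3, 3), dtype=bool)
        nhn = count_hot_neighbors(roi.copy(), roi)
        assert nhn[1, 1, 1] == 6

    def test_worked_two_by_two_by_ten_example(self):
        roi, values = two_by_two_by_ten()
        lab = classify_hot(values[roi])
        hot = scatter_flags(lab.hot_flags, roi)
        nhn = count_hot_neighbors(hot, roi)
        assert nhn[0, 0, 4] == 1 and nhn[0, 0, 5] == 1
        assert nhn[~hot].sum() == 6  # hot-cold face adjacencies

    def test_hot_outside_roi_rejected(self):
        roi = np.zeros((2, 2, 2), dtype=bool)
        hot = np.ones_like(roi)
        with pytest.raises(ValueError):
            count_hot_neighbors(hot, roi)

    def test_matches_all_pairs_oracle_on_random_grids(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            shape = tuple(rng.integers(3, 9, 3))
            roi = rng.random(shape) < 0.7
            hot = roi & (rng.random(shape) < 0.15)
            np.testing.assert_array_equal(
                count_hot_neighbors(hot, roi), brute_force_nhn(roi, hot)
            )


class TestClusterIndex:
    def test_single_hot_voxel_gives_index_zero(self):
        # 20-voxel ROI at the default fraction -> m = 1, so hot NHN must be 0
        values = np.random.default_rng(2).random((2, 2, 5))
        roi = np.ones((2, 2, 5), dtype=bool)
        lab, res = compute_cluster_index(values[roi], roi)
        assert lab.m == 1
        assert res.cluster_index == 0.0

    def test_worked_example_is_one_third(self):
        roi, values = two_by_two_by_ten()
        _, res = compute_cluster_index(values[roi], roi)
        assert res.cluster_index == pytest.approx(1.0 / 3.0)
        assert res.correction_factor == pytest.approx(19.0)

    def test_index_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(3)
        roi = np.ones((8, 8, 8), dtype=bool)
        values = rng.gamma(2.0, 1.0, roi.shape)
        _, a = compute_cluster_index(values[roi], roi)
        _, b = compute_cluster_index(np.log1p(values[roi]) * 7 + 1, roi)
        assert a.cluster_index == pytest.approx(b.cluster_index, rel=1e-12)

    def test_index_zero_when_no_two_hot_voxels_touch(self):
        values = np.random.default_rng(4).random((6, 6, 6))
        values[0, 0, 0] = 9.0
        values[3, 3, 3] = 8.0
        values[5, 5, 5] = 7.0
        roi = np.ones((6, 6, 6), dtype=bool)
        lab, res = compute_cluster_index(values[roi], roi, fraction=3 / 216)
        assert lab.m == 3
        assert res.cluster_index == 0.0

    def test_degenerate_cold_mean_zero_flagged_infinite(self):
        # disconnected ROI: hot pair in one segment, cold pair in the other,
        # so no cold voxel touches a hot one and the denominator vanishes
        roi = np.zeros((1, 1, 5), dtype=bool)
        roi[0, 0, [0, 1, 3, 4]] = True
        hot = np.zeros_like(roi)
        hot[0, 0, [0, 1]] = True
        nhn = count_hot_neighbors(hot, roi)
        lab = classify_hot(np.array([5.0, 5.0, 0.0, 0.0]), fraction=0.5)
        res = cluster_index(lab, nhn[roi])
        assert res.degenerate and np.isinf(res.cluster_index)

    def test_edge_count_identities_on_random_grids(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            shape = tuple(rng.integers(4, 12, 3))
            roi = rng.random(shape) < 0.8
            hot = roi & (rng.random(shape) < 0.1)
            nhn = count_hot_neighbors(hot, roi)
            hot_idx = np.argwhere(hot)
            n_hot_hot = 0
            if len(hot_idx) > 1:
                diff = np.abs(hot_idx[:, None, :] - hot_idx[None, :, :]).sum(axis=2)
                n_hot_hot = int((diff == 1).sum() // 2)
            cold = roi & ~hot
            cold_idx = np.argwhere(cold)
            n_hot_cold = 0
            if len(hot_idx) and len(cold_idx):
                diff = np.abs(cold_idx[:, None, :] - hot_idx[None, :, :]).sum(axis=2)
                n_hot_cold = int((diff == 1).sum())
            assert nhn[hot].sum() == 2 * n_hot_hot
            assert nhn[cold].sum() == n_hot_cold


class TestPermutationNull:
    def test_same_seed_reproduces_null(self):
        rng = np.random.default_rng(8)
        roi = np.ones((10, 10, 10), dtype=bool)
        values = rng.gamma(2.0, 1.0, roi.shape)[roi]
        a = permutation_null(values, roi, n_permutations=50, seed=123)
        b = permutation_null(values, roi, n_permutations=50, seed=123)
        assert a.null_mean == b.null_mean and a.p_value == b.p_value

    def test_compact_blob_achieves_minimum_p(self):
        roi = np.ones((12, 12, 12), dtype=bool)
        values = np.random.default_rng(9).gamma(16.0, 1.0, roi.shape)
        # inflate a compact ball that will own the hot set
        xx, yy, zz = np.meshgrid(*[np.arange(12)] * 3, indexing="ij")
        ball = ((xx - 6) ** 2 + (yy - 6) ** 2 + (zz - 6) ** 2) <= 9
        values[ball] *= 10
        res = permutation_null(values[roi], roi, n_permutations=99, seed=5)
        assert res.p_value == pytest.approx(1.0 / 100.0)
        assert res.observed > 1.0

    def test_random_phantom_not_systematically_significant(self):
        hits = 0
        for s in range(10):
            roi = np.ones((10, 10, 10), dtype=bool)
            values = np.random.default_rng(100 + s).gamma(4.0, 1.0, roi.shape)
            res = permutation_null(values[roi], roi, n_permutations=39, seed=s)
            hits += res.p_value <= 0.05
        assert hits <= 2  # ~uniform p under the null

    def test_blob_beats_scatter_for_fixed_hot_count(self):
        roi = np.ones((12, 12, 12), dtype=bool)
        for s in range(5):
            rng = np.random.default_rng(200 + s)
            base = rng.gamma(16.0, 1.0, roi.shape)
            blob_vals = base.copy()
            xx, yy, zz = np.meshgrid(*[np.arange(12)] * 3, indexing="ij")
            blob_vals[((xx - 6) ** 2 + (yy - 6) ** 2 + (zz - 6) ** 2) <= 9] *= 10
            _, blob_res = compute_cluster_index(blob_vals[roi], roi)
            scatter_vals = base[roi].copy()
            rng.shuffle(scatter_vals)
            _, scatter_res = compute_cluster_index(scatter_vals, roi)
            assert blob_res.cluster_index > scatter_res.cluster_index

    def test_invalid_permutation_count_rejected(self):
        roi = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            permutation_null(np.arange(64.0), roi, n_permutations=0, seed=1)
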