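"""Voxelwise inference and Monte-Carlo cluster-extent correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from alffpipe.errors import InvalidInputError
from alffpipe.groupstats import (
    McThreshold,
    ancova_fmap,
    cluster_mean_alff,
    extract_clusters,
    mc_cluster_threshold,
    one_sample_tmap,
    posthoc_tmap,
    wmh_subgroup_test,
)
from alffpipe.types import AlffMap, StatMap


def _maps_from_matrix(values, shape=(2, 3, 1), mask=None):
    """Build AlffMaps whose in-mask voxel values are the rows of `values`."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    maps = []
    for row in values:
        data = np.zeros(shape)
        data[mask] = row
        maps.append(AlffMap(data=data, band=(0.008, 0.09), mask=mask, normalized=True))
    return maps, mask


class TestOneSample:
    def test_hand_computed_t(self):
        """n=5 values 1.1..1.5 against null 1: t = 0.3/(0.1581/sqrt5) = 4.2426."""
        vals = np.array([[1.1], [1.2], [1.3], [1.4], [1.5]])
        maps, mask = _maps_from_matrix(np.repeat(vals, 6, axis=1))
        stat = one_sample_tmap(maps, null_value=1.0, mask=mask)
        np.testing.assert_allclose(stat.data[mask], 4.242640687, rtol=1e-8)
        assert stat.df == (4.0,)

    def test_subject_order_irrelevant(self, rng):
        vals = rng.normal(1.0, 0.1, size=(6, 6))
        maps, mask = _maps_from_matrix(vals)
        perm = rng.permutation(6)
        maps_p, _ = _maps_from_matrix(vals[perm])
        np.testing.assert_allclose(
            one_sample_tmap(maps, mask=mask).data, one_sample_tmap(maps_p, mask=mask).data
        )

    def test_degenerate_variance_policy(self):
        maps, mask = _maps_from_matrix(np.full((4, 6), 1.3))
        stat = one_sample_tmap(maps, null_value=1.0, mask=mask)
        assert np.all(np.isinf(stat.data[mask]))
        maps_eq, _ = _maps_from_matrix(np.full((4, 6), 1.0))
        stat_eq = one_sample_tmap(maps_eq, null_value=1.0, mask=mask)
        assert np.all(stat_eq.data[mask] == 0.0)

    def test_needs_three_maps(self):
        maps, mask = _maps_from_matrix(np.ones((2, 6)))
        with pytest.raises(InvalidInputError):
            one_sample_tmap(maps, mask=mask)


class TestAncova:
    def test_f_equals_squared_t_for_two_groups(self, rng):
        """With two groups the group-factor F equals the squared t of the
        group coefficient in the same age-adjusted model."""
        import statsmodels.api as sm

        n = 16
        groups = np.array(["CTL"] * 8 + ["SCD"] * 8)
        age = rng.uniform(20, 40, n)
        vals = rng.normal(1.0, 0.1, size=(n, 6))
        maps, mask = _maps_from_matrix(vals)
        fstat = ancova_fmap(maps, groups, age, mask=mask)
        X = sm.add_constant(np.column_stack([(groups == "SCD").astype(float), age]))
        for v in range(6):
            fit = sm.OLS(vals[:, v], X).fit()
            assert fstat.data[mask][v] == pytest.approx(fit.tvalues[1] ** 2, rel=1e-8)

    def test_matches_statsmodels_anova_three_groups(self, rng):
        """Extra-sum-of-squares F for the group factor, cross-checked with a
        statsmodels OLS fit per voxel."""
        import statsmodels.api as sm

        n = 18
        groups = np.repeat(["ACTL", "CTL", "SCD"], 6)
        age = rng.uniform(18, 45, n)
        vals = rng.normal(1.0, 0.1, size=(n, 4))
        maps, mask = _maps_from_matrix(vals, shape=(2, 2, 1))
        fstat = ancova_fmap(maps, groups, age, mask=mask)
        assert fstat.df == (2.0, 14.0)
        d1 = (groups == "CTL").astype(float)
        d2 = (groups == "SCD").astype(float)
        X_full = sm.add_constant(np.column_stack([d1, d2, age]))
        X_red = sm.add_constant(age)
        for v in range(4):
            full = sm.OLS(vals[:, v], X_full).fit()
            red = sm.OLS(vals[:, v], X_red).fit()
            f = ((red.ssr - full.ssr) / 2) / (full.ssr / 14)
            assert fstat.data[mask][v] == pytest.approx(f, rel=1e-8)

    def test_null_calibration_at_voxel_level(self, rng):
        """Shuffled labels under a global null: P(F > F_crit) ~ 0.05."""
        n = 24
        groups = np.repeat(["ACTL", "CTL", "SCD"], 8)
        n_vox = 2000
        vals = rng.normal(size=(n, n_vox))
        mask = np.ones((40, 50, 1), dtype=bool)
        maps, _ = _maps_from_matrix(vals, shape=(40, 50, 1), mask=mask)
        age = rng.uniform(18, 45, n)
        fstat = ancova_fmap(maps, groups, age, mask=mask)
        crit = stats.f.ppf(0.95, *fstat.df)
        rate = float(np.mean(fstat.data[mask] > crit))
        assert 0.03 < rate < 0.07

    def test_identical_maps_give_zero_f(self):
        maps, mask = _maps_from_matrix(np.ones((8, 6)))
        groups = np.array(["CTL"] * 4 + ["SCD"] * 4)
        age = np.array([20.0, 25, 30, 35, 22, 27, 32, 37])
        stat = ancova_fmap(maps, groups, age, mask=mask)
        assert np.all(stat.data[mask] == 0.0)

    def test_age_collinear_with_groups_rejected(self):
        maps, mask = _maps_from_matrix(np.random.default_rng(0).normal(size=(8, 6)))
        groups = np.array(["CTL"] * 4 + ["SCD"] * 4)
        age = np.array([20.0] * 4 + [30.0] * 4)  # age == group indicator
        from alffpipe.errors import NumericalError

        with pytest.raises(NumericalError):
            ancova_fmap(maps, groups, age, mask=mask)


class TestPosthoc:
    def test_hand_computed_pooled_t(self):
        """{2,3,4} vs {1,2,3}: pooled t = 1/sqrt(2/3) = 1.2247, df 4."""
        vals = np.array([[2.0], [3.0], [4.0], [1.0], [2.0], [3.0]])
        maps, mask = _maps_from_matrix(np.repeat(vals, 6, axis=1))
        groups = np.array(["SCD"] * 3 + ["CTL"] * 3)
        stat = posthoc_tmap(maps, groups, "SCD", "CTL", mask)
        np.testing.assert_allclose(stat.data[mask], 1.224744871, rtol=1e-8)
        assert stat.df == (4.0,)

    def test_antisymmetric_in_group_order(self, rng):
        vals = rng.normal(size=(8, 6))
        maps, mask = _maps_from_matrix(vals)
        groups = np.array(["SCD"] * 4 + ["CTL"] * 4)
        ab = posthoc_tmap(maps, groups, "SCD", "CTL", mask)
        ba = posthoc_tmap(maps, groups, "CTL", "SCD", mask)
        np.testing.assert_allclose(ab.data, -ba.data, atol=1e-12)

    def test_identical_groups_give_zero(self):
        vals = np.vstack([np.arange(6.0)] * 2 + [np.arange(6.0)] * 2)
        maps, mask = _maps_from_matrix(vals)
        groups = np.array(["SCD", "SCD", "CTL", "CTL"])
        stat = posthoc_tmap(maps, groups, "SCD", "CTL", mask)
        np.testing.assert_allclose(stat.data[mask], 0.0)

    def test_empty_mask_warns_and_returns_zero_map(self, rng):
        vals = rng.normal(size=(8, 6))
        maps, mask = _maps_from_matrix(vals)
        groups = np.array(["SCD"] * 4 + ["CTL"] * 4)
        empty = np.zeros_like(mask)
        stat = posthoc_tmap(maps, groups, "SCD", "CTL", empty)
        assert np.all(stat.data == 0.0)


def _bernoulli_cluster_oracle(mask, voxel_p, alpha, n_iter, seed, sided="two"):
    """Independent re-implementation of the extent calibration for FWHM=0:
    iid marking of voxels with the stated probability, hand-rolled BFS
    flood fill for face-adjacent components."""
    rng = np.random.default_rng(seed)
    idx = np.argwhere(mask)
    index_of = {tuple(v): i for i, v in enumerate(idx)}
    neighbors = [[] for _ in range(len(idx))]
    for i, v in enumerate(idx):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            j = index_of.get((v[0] + d[0], v[1] + d[1], v[2] + d[2]))
            if j is not None:
                neighbors[i].append(j)

    def max_comp(marked):
        seen = np.zeros(len(idx), dtype=bool)
        best = 0
        for start in range(len(idx)):
            if marked[start] and not seen[start]:
                size, queue = 0, [start]
                seen[start] = True
                while queue:
                    u = queue.pop()
                    size += 1
                    for w in neighbors[u]:
                        if marked[w] and not seen[w]:
                            seen[w] = True
                            queue.append(w)
                best = max(best, size)
        return best

    maxima = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        if sided == "two":
            u = rng.uniform(size=len(idx))
            maxima[it] = max(max_comp(u < voxel_p / 2), max_comp(u > 1 - voxel_p / 2))
        else:
            maxima[it] = max_comp(rng.uniform(size=len(idx)) < voxel_p)
    for k in range(1, int(maxima.max()) + 2):
        if np.mean(maxima >= k) <= alpha:
            return k
    return int(maxima.max()) + 1


class TestMcThreshold:
    def test_matches_independent_bernoulli_oracle_at_fwhm_zero(self):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[1:7, 1:7, 1:3] = True
        mc = McThreshold(voxel_p=0.05, fwhm=0.0, alpha=0.05, n_iter=4000, seed=5)
        ours = mc_cluster_threshold(mask, mc)
        oracle = _bernoulli_cluster_oracle(mask, 0.05, 0.05, 4000, seed=77)
        assert abs(ours - oracle) <= 1

    def test_one_sided_also_matches_oracle(self):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[1:7, 1:7, 1:3] = True
        mc = McThreshold(voxel_p=0.05, fwhm=0.0, alpha=0.05, n_iter=4000, seed=5, sided="one")
        ours = mc_cluster_threshold(mask, mc)
        oracle = _bernoulli_cluster_oracle(mask, 0.05, 0.05, 4000, seed=77, sided="one")
        assert abs(ours - oracle) <= 1

    def test_monotone_in_alpha(self):
        mask = np.ones((10, 10, 4), dtype=bool)
        base = dict(voxel_p=0.05, fwhm=2.0, n_iter=2000, seed=3)
        k_lenient = mc_cluster_threshold(mask, McThreshold(alpha=0.05, **base))
        k_strict = mc_cluster_threshold(mask, McThreshold(alpha=0.01, **base))
        assert k_lenient <= k_strict

    def test_monotone_in_smoothness(self):
        mask = np.ones((12, 12, 6), dtype=bool)
        ks = []
        for fwhm in (0.0, 2.0, 4.0):
            k = mc_cluster_threshold(
                mask, McThreshold(voxel_p=0.05, fwhm=fwhm, alpha=0.05, n_iter=2000, seed=9)
            )
            ks.append(k)
        assert ks[0] <= ks[1] <= ks[2]

    def test_insufficient_iterations_rejected(self):
        mask = np.ones((4, 4, 2), dtype=bool)
        with pytest.raises(InvalidInputError):
            mc_cluster_threshold(mask, McThreshold(alpha=0.001, n_iter=1000))


def _tmap_from_values(data, df=20.0, mask=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    return StatMap(data=data, df=(df,), stat_kind="t", mask=mask, voxel_size=(3.0, 3.0, 3.0))


class TestExtractClusters:
    def test_blob_size_and_filter_rule(self):
        data = np.zeros((6, 6, 2))
        data[1:3, 1:3, 0] = 10.0  # 4-voxel blob
        data[4:6, 4:6, :] = 10.0  # 8-voxel blob
        stat = _tmap_from_values(data)
        table = extract_clusters(stat, 0.05, min_cluster_voxels=5).table
        assert len(table) == 1
        assert table.iloc[0]["size_voxels"] == 8
        assert table.iloc[0]["size_mm3"] == pytest.approx(8 * 27.0)
        empty = extract_clusters(stat, 0.05, min_cluster_voxels=9).table
        assert len(empty) == 0

    def test_corner_touching_blobs_are_two_clusters(self):
        """Face adjacency: diagonal contact does not merge components."""
        data = np.zeros((6, 6, 1))
        data[1:3, 1:3, 0] = 10.0
        data[3:5, 3:5, 0] = 10.0  # touches only at the (2,2)/(3,3) corner
        clusters = extract_clusters(_tmap_from_values(data), 0.05, 1)
        assert len(clusters) == 2
        assert sorted(clusters.table["size_voxels"]) == [4, 4]
        # with corner adjacency allowed the blobs would merge into one
        _, n_full = ndimage.label(data[:, :, 0] > 0, structure=np.ones((3, 3)))
        assert n_full == 1

    def test_negative_clusters_reported_with_sign(self):
        data = np.zeros((6, 6, 2))
        data[1:4, 1:4, :] = -8.0
        table = extract_clusters(_tmap_from_values(data), 0.05, 1).table
        assert set(table["sign"]) == {-1}
        assert table.iloc[0]["mean_stat"] < 0

    def test_peak_is_max_abs_statistic(self):
        data = np.zeros((6, 6, 1))
        data[1:4, 1, 0] = (5.0, 9.0, 6.0)
        table = extract_clusters(_tmap_from_values(data), 0.05, 1).table
        assert (table.iloc[0]["peak_i"], table.iloc[0]["peak_j"]) == (2, 1)
        assert table.iloc[0]["peak_x_mm"] == pytest.approx(2 * 3.0)


class TestClusterMeanAlff:
    def test_uniform_and_simple_means(self):
        mask = np.ones((3, 3, 1), dtype=bool)
        data = np.zeros((3, 3, 1))
        data[0, :, 0] = (1.0, 2.0, 3.0)
        amap = AlffMap(data=data, band=(0.008, 0.09), mask=mask)
        cluster = np.zeros((3, 3, 1), dtype=bool)
        cluster[0, :, 0] = True
        assert cluster_mean_alff(amap, cluster) == pytest.approx(2.0)

    def test_union_mean_is_size_weighted(self, rng):
        mask = np.ones((4, 4, 2), dtype=bool)
        amap = AlffMap(data=rng.uniform(size=(4, 4, 2)), band=(0.008, 0.09), mask=mask)
        a = np.zeros((4, 4, 2), dtype=bool)
        b = np.zeros((4, 4, 2), dtype=bool)
        a[0, :, 0] = True  # 4 voxels
        b[2, :2, 1] = True  # 2 voxels
        union = cluster_mean_alff(amap, a | b)
        weighted = (4 * cluster_mean_alff(amap, a) + 2 * cluster_mean_alff(amap, b)) / 6
        assert union == pytest.approx(weighted)

    def test_empty_cluster_rejected(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        amap = AlffMap(data=np.ones((2, 2, 1)), band=(0.008, 0.09), mask=mask)
        with pytest.raises(InvalidInputError):
            cluster_mean_alff(amap, np.zeros((2, 2, 1), dtype=bool))


class TestWmhSubgroup:
    def _clusters(self, shape=(6, 6, 2)):
        data = np.zeros(shape)
        data[1:4, 1:4, :] = 10.0
        return extract_clusters(_tmap_from_values(data), 0.05, 1)

    def test_identical_flags_rejected(self, rng):
        maps, _ = _maps_from_matrix(rng.normal(size=(6, 72)), shape=(6, 6, 2))
        with pytest.raises(InvalidInputError):
            wmh_subgroup_test(maps, np.ones(6, dtype=bool), self._clusters())

    def test_planted_decrement_recovered_with_negative_t(self, rng):
        clusters = self._clusters()
        vox = clusters.voxels(1)
        flags = np.array([True] * 5 + [False] * 5)
        maps = []
        for flag in flags:
            data = np.ones((6, 6, 2)) + 0.02 * rng.normal(size=(6, 6, 2))
            if flag:
                data[vox] -= 0.5
            maps.append(AlffMap(data=data, band=(0.008, 0.09), mask=np.ones((6, 6, 2), bool)))
        sub = wmh_subgroup_test(maps, flags, clusters, voxel_p=0.05, min_cluster_voxels=1)
        assert len(sub) >= 1
        assert (sub["mean_t"] < 0).all()

    def test_null_rarely_yields_subclusters(self, rng):
        """Without any planted effect, sub-cluster tables are usually empty
        once a realistic extent rule applies."""
        clusters = self._clusters()
        flags = np.array([True] * 5 + [False] * 5)
        n_hit = 0
        for rep in range(20):
            maps = [
                AlffMap(
                    data=1.0 + 0.05 * rng.normal(size=(6, 6, 2)),
                    band=(0.008, 0.09),
                    mask=np.ones((6, 6, 2), bool),
                )
                for _ in range(10)
            ]
            sub = wmh_subgroup_test(maps, flags, clusters, voxel_p=0.05, min_cluster_voxels=4)
            if len(sub):
                n_hit += 1
        assert n_hit <= 4
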