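import numpy as np
import pytest
from scipy import stats

import hemipark as hp
from hemipark.core import Image3D
from hemipark.spm import connectivity_structure

from oracles import brute_force_tfce


def imgs_from(data):
    return [Image3D(d, (1, 1, 1)) for d in data]


class TestTwoSampleTMap:
    def test_identical_groups_zero(self, rng):
        data = rng.normal(size=(3, 4, 4, 4))
        sm = hp.twosample_tmap(imgs_from(data), imgs_from(data.copy()))
        assert np.allclose(sm.image.values, 0.0)

    def test_zero_pooled_variance_warns_and_zeroes(self, rng):
        a = rng.normal(size=(3, 2, 2, 2))
        b = rng.normal(size=(3, 2, 2, 2))
        a[:, 0, 0, 0] = b[:, 0, 0, 0] = 1.0  # degenerate voxel
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            sm = hp.twosample_tmap(imgs_from(a), imgs_from(b))
        assert sm.image.values[0, 0, 0] == 0.0

    def test_df_rule_7v6(self, rng):
        sm = hp.twosample_tmap(
            imgs_from(rng.normal(size=(7, 3, 3, 3))),
            imgs_from(rng.normal(size=(6, 3, 3, 3))),
        )
        assert sm.df == 11

    def test_matches_scipy_pooled_t(self, rng):
        a = rng.normal(size=(3, 2, 1, 1))
        b = rng.normal(size=(3, 2, 1, 1))
        sm = hp.twosample_tmap(imgs_from(a), imgs_from(b))
        for idx in np.ndindex(2, 1, 1):
            t_ref = stats.ttest_ind(a[(slice(None),) + idx], b[(slice(None),) + idx]).statistic
            assert sm.image.values[idx] == pytest.approx(t_ref, abs=1e-12)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            hp.twosample_tmap(imgs_from(rng.normal(size=(1, 2, 2, 2))), imgs_from(rng.normal(size=(3, 2, 2, 2))))


class TestCorrelationRMap:
    def test_self_covariate_r_one(self, rng):
        data = rng.normal(size=(5, 3, 3, 3))
        cov = data[:, 1, 1, 1]
        sm = hp.correlation_rmap(imgs_from(data), cov)
        assert sm.image.values[1, 1, 1] == pytest.approx(1.0)
        assert sm.n == 5

    def test_matches_scipy_pearson(self, rng):
        data = rng.normal(size=(5, 2, 2, 1))
        cov = rng.normal(size=5)
        sm = hp.correlation_rmap(imgs_from(data), cov)
        for idx in np.ndindex(2, 2, 1):
            r_ref = stats.pearsonr(cov, data[(slice(None),) + idx]).statistic
            assert sm.image.values[idx] == pytest.approx(r_ref, abs=1e-12)

    def test_null_r_distribution_small(self, rng):
        data = rng.normal(size=(40, 6, 6, 6))
        cov = rng.normal(size=40)
        sm = hp.correlation_rmap(imgs_from(data), cov)
        assert np.abs(sm.image.values).mean() < 0.25
        assert np.all(np.abs(sm.image.values) <= 1.0)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            hp.correlation_rmap(imgs_from(rng.normal(size=(5, 2, 2, 2))), np.ones(5))


class TestTFCE:
    def test_all_zero_map(self):
        res = hp.tfce_enhance(Image3D(np.zeros((4, 4, 4)), (1, 1, 1)))
        assert np.all(res.enhanced_pos.values == 0)
        assert np.all(res.enhanced_neg.values == 0)

    def test_single_voxel_analytic_limit(self):
        h = 3.0
        v = np.zeros((7, 7, 7))
        v[3, 3, 3] = h
        res = hp.tfce_enhance(Image3D(v, (1, 1, 1)), E=0.5, H=2.0, n_steps=1000)
        assert res.enhanced_pos.values[3, 3, 3] == pytest.approx(h**3 / 3, rel=0.02)

    @pytest.mark.parametrize("E,H,conn", [(0.5, 2.0, 6), (1.0, 1.0, 26), (0.5, 1.0, 18)])
    def test_matches_bruteforce(self, rng, E, H, conn):
        for _ in range(5):
            v = rng.normal(size=(4, 4, 4))
            res = hp.tfce_enhance(Image3D(v, (1, 1, 1)), E=E, H=H, n_steps=17, connectivity=conn)
            expected = brute_force_tfce(v, E, H, 17, conn)
            got = res.enhanced_pos.values - res.enhanced_neg.values
            signed_expected = np.where(v > 0, expected, -expected)
            np.testing.assert_allclose(got, signed_expected, rtol=1e-9, atol=1e-12)

    def test_monotone_in_statistic(self, rng):
        # raising a (non-maximal, so the threshold ladder is unchanged)
        # voxel's statistic never decreases any enhanced value
        for _ in range(5):
            v = rng.normal(size=(5, 5, 5))
            base = hp.tfce_enhance(Image3D(v, (1, 1, 1)), n_steps=40).enhanced_pos.values
            v2 = v.copy()
            flat = np.argsort(v, axis=None)
            i = np.unravel_index(flat[rng.integers(0, v.size - 1)], v.shape)
            v2[i] = min(v2[i] + 0.5, v.max())
            bumped = hp.tfce_enhance(Image3D(v2, (1, 1, 1)), n_steps=40).enhanced_pos.values
            assert np.all(bumped >= base - 1e-12)

    def test_scale_behaviour_single_voxel(self):
        # multiplying the map by c scales single-voxel enhancement by c^(H+1)
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 1.5
        e1 = hp.tfce_enhance(Image3D(v, (1, 1, 1)), n_steps=500).enhanced_pos.values[2, 2, 2]
        e3 = hp.tfce_enhance(Image3D(3 * v, (1, 1, 1)), n_steps=500).enhanced_pos.values[2, 2, 2]
        assert e3 / e1 == pytest.approx(3.0 ** 3, rel=1e-6)

    def test_zero_where_statistic_zero(self, rng):
        v = np.zeros((5, 5, 5))
        v[0, 0, 0] = 2.0
        res = hp.tfce_enhance(Image3D(v, (1, 1, 1)), n_steps=20)
        assert res.enhanced_pos.values[4, 4, 4] == 0.0

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            hp.tfce_enhance(Image3D(np.zeros((3, 3, 3)), (1, 1, 1)), n_steps=0)


class TestPermutationInference:
    def _small_design(self, rng, shape=(5, 5, 4), n_a=4, n_b=3):
        data = rng.normal(size=(n_a + n_b,) + shape)
        design = np.array(["a"] * n_a + ["b"] * n_b)
        return imgs_from(data), design

    def test_exhaustive_small_design(self, rng):
        imgs, design = self._small_design(rng)
        inf = hp.permutation_inference(imgs, design, n_perm=50, n_steps=15)
        assert inf.scheme == "exhaustive"
        assert inf.n_effective == 35  # C(7,3)
        mult = inf.corrected_p.values * 35
        assert np.allclose(mult, np.round(mult), atol=1e-9)

    def test_monte_carlo_min_p(self, rng):
        imgs, design = self._small_design(rng)
        inf = hp.permutation_inference(
            imgs, design, n_perm=40, n_steps=15, max_exhaustive=10
        )
        assert inf.scheme == "monte_carlo"
        assert inf.corrected_p.values.min() >= 1 / 41 - 1e-12

    def test_corrected_dominates_voxelwise(self, rng):
        # max-statistic corrected p is never below the uncorrected
        # voxel-level permutation p computed from the same relabelings
        import itertools

        data = rng.normal(size=(7, 4, 4, 3))
        data[:4] += 1.0
        imgs = imgs_from(data)
        design = np.array(["a"] * 4 + ["b"] * 3)
        inf = hp.permutation_inference(imgs, design, n_perm=50, n_steps=15)
        X = data.reshape(7, -1)
        null_maps = []
        for combo in itertools.combinations(range(7), 4):
            is_a = np.zeros(7, bool)
            is_a[list(combo)] = True
            t = hp.spm._group_t_flat(X, is_a).reshape(4, 4, 3)
            enh = hp.tfce_enhance(Image3D(t, (1, 1, 1)), n_steps=15)
            null_maps.append(enh.enhanced_pos.values)
        null_maps = np.array(null_maps)
        obs = inf.observed.enhanced_pos.values
        p_voxel = (null_maps >= obs[None]).mean(axis=0)
        pos = inf.statmap.image.values > 0
        assert np.all(inf.corrected_p.values[pos] >= p_voxel[pos] - 1e-12)

    def test_correlation_design_shuffles_covariate(self, rng):
        data = rng.normal(size=(6, 4, 4, 3))
        cov = rng.normal(size=6)
        inf = hp.permutation_inference(
            imgs_from(data), cov, statistic="correlation", n_perm=60,
            n_steps=15, max_exhaustive=10, seed=5,
        )
        assert inf.scheme == "monte_carlo"
        assert inf.statmap.kind == "r"
        assert np.all(np.abs(inf.statmap.image.values) <= 1)

    def test_validation_errors(self, rng):
        imgs, design = self._small_design(rng)
        with pytest.raises(ValueError, match="n_perm"):
            hp.permutation_inference(imgs, design, n_perm=5)
        with pytest.raises(ValueError, match="duplicate"):
            hp.permutation_inference(
                imgs, design, n_perm=20, subject_ids=["s1"] * len(imgs)
            )
        with pytest.raises(ValueError, match="two levels"):
            hp.permutation_inference(imgs, np.array(["a"] * 7), n_perm=20)


class TestThresholdAndClusters:
    def test_alpha_below_minimum_empty(self, rng):
        data = rng.normal(size=(7, 4, 4, 3))
        design = np.array(["a"] * 4 + ["b"] * 3)
        inf = hp.permutation_inference(imgs_from(data), design, n_perm=50, n_steps=10)
        thr = hp.threshold_map(inf, 1e-6)
        assert np.count_nonzero(thr.values) == 0

    def test_alpha_one_passes_all(self, rng):
        data = rng.normal(size=(7, 4, 4, 3))
        design = np.array(["a"] * 4 + ["b"] * 3)
        inf = hp.permutation_inference(imgs_from(data), design, n_perm=50, n_steps=10)
        thr = hp.threshold_map(inf, 1.0)
        assert np.count_nonzero(thr.values) == thr.values.size

    def test_diagonal_voxels_connectivity(self):
        m = np.zeros((4, 4, 4), dtype=np.int8)
        m[1, 1, 1] = 1
        m[2, 2, 2] = 1
        img = Image3D(m, (1, 1, 1))
        assert len(hp.clusters_to_vois(img, connectivity=6)) == 2
        assert len(hp.clusters_to_vois(img, connectivity=26)) == 1

    def test_empty_map_no_vois(self):
        img = Image3D(np.zeros((4, 4, 4), dtype=np.int8), (1, 1, 1))
        assert hp.clusters_to_vois(img) == []

    def test_signs_split_and_majority_naming(self, atlas):
        m = np.zeros(atlas.shape, dtype=np.int8)
        m[atlas.mask("rfa_L")] = -1
        m[atlas.mask("mlr_R")] = 1
        img = Image3D(m, atlas.voxel_size)
        vois = hp.clusters_to_vois(img, atlas=atlas)
        names = {(v.name, v.sign) for v in vois}
        assert ("rfa_L", -1) in names
        assert ("mlr_R", 1) in names

    def test_connectivity_structure_counts(self):
        assert len(connectivity_structure(6)) == 6
        assert len(connectivity_structure(18)) == 18
        assert len(connectivity_structure(26)) == 26
        with pytest.raises(ValueError):
            connectivity_structure(10)
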