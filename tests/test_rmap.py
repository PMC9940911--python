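import numpy as np
import pytest

from rlddm.rmap import (RMap, VoxelMapStack, heatmap_overlap, permutation_test,
                        predict_behaviour, spatial_similarity, voxelwise_rmap)
from rlddm.task import synth_voxel_cohort


def _mask(dims, frac=0.25):
    m = np.zeros(dims, bool)
    m[: max(1, int(dims[0] * frac))] = True
    return m


class TestVoxelwiseRmap:
    def test_planted_signal_recovered_above_background(self):
        rng = np.random.default_rng(0)
        dims = (8, 8, 8)
        mask = _mask(dims)
        stack, beh = synth_voxel_cohort(20, dims, mask, 0.8, 1.0, rng)
        rmap = voxelwise_rmap(VoxelMapStack(stack), beh)
        assert np.abs(rmap.values[mask]).mean() > 2 * np.abs(rmap.values[~mask]).mean()
        assert np.all(np.abs(rmap.values) <= 1.0)

    def test_constant_behaviour_rejected(self):
        stack = VoxelMapStack(np.random.default_rng(1).normal(size=(6, 4, 4, 4)))
        with pytest.raises(ValueError, match="variance"):
            voxelwise_rmap(stack, np.ones(6))

    def test_permuted_behaviour_centres_at_zero(self):
        rng = np.random.default_rng(2)
        dims = (6, 6, 6)
        stack, beh = synth_voxel_cohort(30, dims, _mask(dims), 0.9, 1.0, rng)
        rmap = voxelwise_rmap(VoxelMapStack(stack), rng.permutation(beh))
        assert abs(rmap.values[rmap.mask].mean()) < 0.1

    def test_two_subject_stack_warns_with_unit_correlations(self):
        rng = np.random.default_rng(3)
        stack = VoxelMapStack(rng.normal(size=(2, 3, 3, 3)))
        with pytest.warns(UserWarning, match="2"):
            rmap = voxelwise_rmap(stack, np.array([0.0, 1.0]))
        assert np.allclose(np.abs(rmap.values[rmap.mask]), 1.0)

    def test_threshold_zeroes_subthreshold_voxels(self):
        rng = np.random.default_rng(4)
        stack = VoxelMapStack(rng.normal(size=(10, 4, 4, 4)))
        beh = rng.normal(size=10)
        full = voxelwise_rmap(stack, beh)
        thr = voxelwise_rmap(stack, beh, threshold=0.5)
        sub = np.abs(full.values) < 0.5
        assert np.all(thr.values[sub & full.mask] == 0.0)


class TestSpatialSimilarity:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(4, 4, 4))
        rmap = RMap(values=vals, mask=np.ones((4, 4, 4), bool))
        assert spatial_similarity(vals, rmap) == pytest.approx(1.0)
        assert spatial_similarity(-vals, rmap) == pytest.approx(-1.0)

    def test_independent_noise_is_uncorrelated_on_average(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(6, 6, 6))
        rmap = RMap(values=vals, mask=np.ones((6, 6, 6), bool))
        sims = [spatial_similarity(rng.normal(size=(6, 6, 6)), rmap)
                for _ in range(200)]
        assert abs(np.mean(sims)) < 3 / np.sqrt(200 * 6 ** 3 / 2)

    def test_grid_mismatch_rejected(self):
        rmap = RMap(values=np.zeros((4, 4, 4)), mask=np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError):
            spatial_similarity(np.zeros((5, 5, 5)), rmap)


class TestPredictBehaviour:
    def test_perfect_linear_relation(self):
        x = np.linspace(0, 1, 10)
        r2, p = predict_behaviour(x, 3.0 * x - 1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_r2_is_squared_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r2, _ = predict_behaviour(x, y)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_behaviour(np.ones(10), np.arange(10.0))


class TestPermutationTest:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(8)
        dims = (8, 8, 8)
        stack, beh = synth_voxel_cohort(14, dims, _mask(dims), 0.85, 1.0, rng)
        res = permutation_test(VoxelMapStack(stack), beh, n_perm=200, rng=rng)
        assert res.observed_r > 0
        assert res.p_two_sided < 0.05
        assert 0 < res.p_two_sided <= 1

    def test_minimum_permutations_enforced(self):
        rng = np.random.default_rng(9)
        stack, beh = synth_voxel_cohort(8, (4, 4, 4), _mask((4, 4, 4)), 0.5, 1.0, rng)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(VoxelMapStack(stack), beh, n_perm=10, rng=rng)


class TestHeatmapOverlap:
    def test_volume_inside_region_scores_its_voxel_count(self):
        vol = np.zeros((1, 6, 6, 6), bool)
        vol[0, 2:4, 2:4, 2:4] = True
        region = np.ones((6, 6, 6), bool)
        nmap, scores = heatmap_overlap(vol, {"GPi": region})
        assert scores["GPi"] == 8.0
        assert nmap.max() == 1

    def test_additivity_over_subjects(self):
        vol = np.zeros((1, 5, 5, 5), bool)
        vol[0, 1:3, 1:3, 1:3] = True
        region = np.ones((5, 5, 5), bool)
        _, s1 = heatmap_overlap(vol, {"r": region})
        nmap2, s2 = heatmap_overlap(np.repeat(vol, 2, axis=0), {"r": region})
        assert s2["r"] == 2 * s1["r"]
        assert nmap2.max() == 2

    def test_disjoint_volume_scores_zero(self):
        vol = np.zeros((1, 6, 6, 6), bool)
        vol[0, :2] = True
        region = np.zeros((6, 6, 6), bool)
        region[4:] = True
        _, scores = heatmap_overlap(vol, {"r": region})
        assert scores["r"] == 0.0

    def test_probabilistic_region_binarised_at_threshold(self):
        vol = np.ones((1, 3, 3, 3), bool)
        region = np.full((3, 3, 3), 0.4)
        region[0] = 0.9
        _, scores = heatmap_overlap(vol, {"r": region}, prob_threshold=0.5)
        assert scores["r"] == 9.0

    def test_grid_mismatch_rejected(self):
        vol = np.zeros((1, 4, 4, 4), bool)
        with pytest.raises(ValueError, match="resample"):
            heatmap_overlap(vol, {"r": np.zeros((5, 5, 5), bool)})


class TestNiftiRoundTrip:
    def test_stack_round_trips_through_nifti(self, tmp_path):
        rng = np.random.default_rng(10)
        stack = VoxelMapStack(rng.normal(size=(3, 5, 5, 5)), voxel_size=(2.0, 2.0, 2.0))
        paths = stack.to_nifti(str(tmp_path / "maps"))
        back = VoxelMapStack.from_nifti(paths)
        np.testing.assert_allclose(back.data, stack.data, atol=1e-6)
        assert back.voxel_size == (2.0, 2.0, 2.0)
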