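"""Evaluation metrics against brute-force oracles and hand computations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ffdreg import (
    BinaryMask,
    LandmarkSet,
    Volume3D,
    avg_misalignment,
    dsc,
    gray_contrast,
    hausdorff,
    landmark_dislocation,
    roi_intensity_std,
    sigma_reduction,
    uniformity,
)
from ffdreg.errors import MetricError


def cube_mask(shape, lo, hi):
    data = np.zeros(shape, dtype=np.uint8)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return BinaryMask(data)


class TestDice:
    def test_identical_masks_give_one(self):
        A = cube_mask((10, 10, 10), (2, 2, 2), (7, 7, 7))
        assert dsc(A, A) == 1.0

    def test_disjoint_masks_give_zero(self):
        A = cube_mask((10, 10, 10), (0, 0, 0), (3, 3, 3))
        B = cube_mask((10, 10, 10), (5, 5, 5), (9, 9, 9))
        assert dsc(A, B) == 0.0

    def test_nested_masks_match_voxel_count_oracle(self):
        # |A| = 100, |B| = 200, A inside B: Dice = 2*100/300; the printed
        # union-denominator variant would give 1 here
        A = cube_mask((12, 12, 12), (0, 0, 0), (10, 10, 1))
        B = cube_mask((12, 12, 12), (0, 0, 0), (10, 10, 2))
        assert dsc(A, B) == pytest.approx(2.0 / 3.0)
        assert dsc(A, B, printed_variant=True) == pytest.approx(1.0)

    def test_symmetric_and_bounded_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A = BinaryMask((rng.uniform(size=(8, 8, 8)) > 0.4).astype(np.uint8))
            B = BinaryMask((rng.uniform(size=(8, 8, 8)) > 0.6).astype(np.uint8))
            d = dsc(A, B)
            assert d == dsc(B, A)
            assert 0.0 <= d <= 1.0

    def test_geometry_mismatch_rejected(self):
        A = cube_mask((8, 8, 8), (1, 1, 1), (4, 4, 4))
        B = BinaryMask(A.data, spacing=(2, 1, 1))
        with pytest.raises(MetricError):
            dsc(A, B)


class TestContourDistances:
    def test_identical_sets_give_zero(self):
        pts = np.random.default_rng(1).normal(size=(50, 3))
        assert hausdorff(pts, pts) == 0.0
        assert avg_misalignment(pts, pts) == 0.0

    def test_parallel_planes_distance(self):
        xy = np.stack(np.meshgrid(np.arange(5.0), np.arange(5.0)), -1).reshape(-1, 2)
        a = np.column_stack([xy, np.zeros(len(xy))])
        b = np.column_stack([xy, np.full(len(xy), 2.5)])
        assert hausdorff(a, b) == pytest.approx(2.5)
        assert avg_misalignment(a, b) == pytest.approx(2.5)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(120, 3))
        b = rng.normal(size=(80, 3)) + 0.5
        d_ab = np.array([min(np.linalg.norm(b - p, axis=1)) for p in a])
        d_ba = np.array([min(np.linalg.norm(a - p, axis=1)) for p in b])
        assert hausdorff(a, b) == pytest.approx(max(d_ab.max(), d_ba.max()), abs=1e-10)
        pooled = (d_ab.sum() + d_ba.sum()) / (len(a) + len(b))
        assert avg_misalignment(a, b) == pytest.approx(pooled, abs=1e-10)
        unweighted = 0.5 * (d_ab.mean() + d_ba.mean())
        assert avg_misalignment(a, b, weighted=False) == pytest.approx(unweighted,
                                                                       abs=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 40), st.integers(2, 40), st.integers(0, 1000))
    def test_hausdorff_dominates_average_misalignment(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(na, 3)), rng.normal(size=(nb, 3))
        assert hausdorff(a, b) >= avg_misalignment(a, b) - 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(MetricError):
            hausdorff(np.zeros((0, 3)), np.zeros((3, 3)))


class TestUniformity:
    def test_constant_regions_give_one(self):
        vol = Volume3D(np.zeros((8, 8, 8)))
        vol.data[:4] = 10.0
        r1 = cube_mask((8, 8, 8), (0, 0, 0), (4, 8, 8))
        r2 = cube_mask((8, 8, 8), (4, 0, 0), (8, 8, 8))
        assert uniformity(vol, [r1, r2]) == pytest.approx(1.0)

    def test_half_half_binary_region_gives_half(self):
        data = np.zeros((8, 8, 8))
        data[:, :, :4] = 0.0
        data[:, :, 4:] = 40.0
        vol = Volume3D(data)
        region = cube_mask((8, 8, 8), (0, 0, 0), (8, 8, 8))
        # sigma^2 = g^2/4, sigma_max^2 = g^2/2 -> U = 0.5
        assert uniformity(vol, [region]) == pytest.approx(0.5)

    def test_invariant_under_affine_intensity_rescaling(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 100, (8, 8, 8))
        r1 = cube_mask((8, 8, 8), (0, 0, 0), (4, 8, 8))
        r2 = cube_mask((8, 8, 8), (5, 0, 0), (8, 8, 8))
        u1 = uniformity(Volume3D(data), [r1, r2])
        u2 = uniformity(Volume3D(3.5 * data - 17.0), [r1, r2])
        assert u1 == pytest.approx(u2, abs=1e-12)
        assert u1 <= 1.0

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 10, (6, 6, 6))
        vol = Volume3D(data)
        r1 = cube_mask((6, 6, 6), (0, 0, 0), (3, 6, 6))
        r2 = cube_mask((6, 6, 6), (3, 0, 0), (6, 6, 6))
        vals = [data[r.data.astype(bool)] for r in (r1, r2)]
        g = np.concatenate(vals)
        smax2 = (g.max() - g.min()) ** 2 / 2
        num = sum(len(v) * np.mean((v - v.mean()) ** 2) for v in vals)
        expected = 1 - num / (len(g) * smax2)
        assert uniformity(vol, [r1, r2]) == pytest.approx(expected, abs=1e-10)

    def test_zero_dynamic_range_rejected(self):
        vol = Volume3D(np.full((6, 6, 6), 4.0))
        with pytest.raises(MetricError):
            uniformity(vol, [cube_mask((6, 6, 6), (1, 1, 1), (4, 4, 4))])


class TestGrayContrast:
    def test_equal_means_give_zero_and_three_vs_one_gives_half(self):
        data = np.ones((8, 8, 8))
        region = cube_mask((8, 8, 8), (0, 0, 0), (4, 8, 8))
        bg = cube_mask((8, 8, 8), (4, 0, 0), (8, 8, 8))
        assert gray_contrast(Volume3D(data), region, bg) == 0.0
        data2 = np.where(region.data.astype(bool), 3.0, 1.0)
        assert gray_contrast(Volume3D(data2), region, bg) == pytest.approx(0.5)

    def test_matches_direct_mean_computation(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(1, 9, (8, 8, 8))
        region = cube_mask((8, 8, 8), (0, 0, 0), (3, 8, 8))
        bg = cube_mask((8, 8, 8), (5, 0, 0), (8, 8, 8))
        f0 = data[region.data.astype(bool)].mean()
        fb = data[bg.data.astype(bool)].mean()
        assert gray_contrast(Volume3D(data), region, bg) == pytest.approx(
            abs(f0 - fb) / (f0 + fb), abs=1e-12)

    def test_overlapping_masks_rejected(self):
        region = cube_mask((8, 8, 8), (0, 0, 0), (5, 8, 8))
        bg = cube_mask((8, 8, 8), (4, 0, 0), (8, 8, 8))
        with pytest.raises(MetricError):
            gray_contrast(Volume3D(np.ones((8, 8, 8))), region, bg)


class TestSigma:
    def test_constant_roi_has_zero_sigma(self):
        vol = Volume3D(np.full((6, 6, 6), 3.0))
        roi = cube_mask((6, 6, 6), (1, 1, 1), (4, 4, 4))
        assert roi_intensity_std(vol, roi) == 0.0

    def test_reduction_convention_on_reported_group_means(self):
        # elastic registration: sigma 122.43 -> 64.19 is a 47.57% reduction;
        # rigid: 122.43 -> 76.36 is 37.63%
        assert sigma_reduction(122.43, 64.19) == pytest.approx(47.57, abs=0.005)
        assert sigma_reduction(122.43, 76.36) == pytest.approx(37.63, abs=0.005)

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(6)
        data = rng.normal(10, 3, (8, 8, 8))
        roi = cube_mask((8, 8, 8), (2, 2, 2), (6, 6, 6))
        vals = data[roi.data.astype(bool)]
        expected = np.sqrt(np.mean((vals - vals.mean()) ** 2))
        assert roi_intensity_std(Volume3D(data), roi) == pytest.approx(expected,
                                                                       abs=1e-12)


class TestLandmarks:
    def test_identical_sets_give_zeros(self):
        L = LandmarkSet(["a", "b"], [[0, 0, 0], [1, 1, 1]])
        d, mean, sd = landmark_dislocation(L, L)
        assert all(v == 0 for v in d.values()) and mean == 0 and sd == 0

    def test_3_4_0_offset_gives_five(self):
        L1 = LandmarkSet(["a", "b"], [[0, 0, 0], [10, 10, 10]])
        L2 = LandmarkSet(["b", "a"], [[13, 14, 10], [3, 4, 0]])
        d, mean, sd = landmark_dislocation(L1, L2)
        assert d == {"a": 5.0, "b": 5.0}
        assert mean == 5.0 and sd == 0.0

    def test_mean_sd_match_hand_computation(self):
        rng = np.random.default_rng(7)
        p1 = rng.normal(size=(4, 3))
        p2 = rng.normal(size=(4, 3))
        labels = list("wxyz")
        d, mean, sd = landmark_dislocation(LandmarkSet(labels, p1),
                                           LandmarkSet(labels, p2))
        dists = np.linalg.norm(p1 - p2, axis=1)
        assert mean == pytest.approx(dists.mean(), abs=1e-12)
        assert sd == pytest.approx(dists.std(), abs=1e-12)

    def test_label_mismatch_rejected(self):
        with pytest.raises(MetricError):
            landmark_dislocation(LandmarkSet(["a"], [[0, 0, 0]]),
                                 LandmarkSet(["b"], [[0, 0, 0]]))

    def test_csv_round_trip(self, tmp_path):
        L = LandmarkSet(["lm1", "lm2"], [[1.5, 2.0, 3.0], [4.0, 5.5, 6.0]])
        L.to_csv(tmp_path / "lm.csv")
        back = LandmarkSet.from_csv(tmp_path / "lm.csv")
        assert back.labels == L.labels
        np.testing.assert_allclose(back.points, L.points)
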