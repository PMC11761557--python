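"""Pseudo-label synthesis: closed-form Gaussian values, brute-force
equivalence for the Voronoi partition and distance transform, and the
structure of the ternary labels."""

import numpy as np
import pytest

from pointseg.core import BACKGROUND, FOREGROUND, IGNORED, CentroidSet
from pointseg.pseudolabels import (
    distance_transform,
    gaussian_mask,
    gaussian_stack,
    initial_cluster_label,
    voronoi_label,
    voronoi_partition,
    voronoi_ridges,
)


# --------------------------------------------------------- gaussian masks
class TestGaussianMask:
    def test_peak_value_one_at_point(self):
        pts = CentroidSet.from_points([(8, 8)])
        m = gaussian_mask(pts, radius=9, sigma=3, shape=(17, 17))
        assert m[8, 8] == pytest.approx(1.0)

    def test_zero_at_and_beyond_radius(self):
        pts = CentroidSet.from_points([(8, 8)])
        m = gaussian_mask(pts, radius=5, sigma=5 / 3, shape=(17, 17))
        assert m[8, 13] == 0.0  # d = 5 = radius
        assert m[8, 16] == 0.0
        assert m[8, 12] > 0.0   # d = 4 < radius

    def test_closed_form_value(self):
        # d=3 with sigma=3: exp(-9 / (2*9)) = exp(-1/2)
        pts = CentroidSet.from_points([(8, 8)])
        m = gaussian_mask(pts, radius=9, sigma=3, shape=(17, 17))
        assert m[8, 11] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_empty_points_all_zero(self):
        m = gaussian_mask(CentroidSet.empty(), radius=9, sigma=3, shape=(5, 5))
        assert not m.any()

    def test_monotone_decay_with_distance(self):
        pts = CentroidSet.from_points([(16, 16)])
        m = gaussian_mask(pts, radius=13, sigma=13 / 3, shape=(33, 33))
        row = m[16, 16:29]
        assert np.all(np.diff(row) <= 0)

    def test_invalid_parameters(self):
        pts = CentroidSet.from_points([(1, 1)])
        with pytest.raises(ValueError):
            gaussian_mask(pts, radius=0, sigma=1, shape=(4, 4))
        with pytest.raises(ValueError):
            gaussian_mask(pts, radius=5, sigma=-1, shape=(4, 4))


class TestGaussianStack:
    def test_default_four_branches_sigma_third_of_radius(self):
        pts = CentroidSet.from_points([(20, 20)])
        stack = gaussian_stack(pts, (41, 41))
        assert stack.masks.shape[0] == 4
        assert stack.radii == (7.0, 9.0, 11.0, 13.0)
        assert stack.bandwidths == tuple(r / 3 for r in (7.0, 9.0, 11.0, 13.0))

    def test_single_radius_equals_single_mask(self):
        pts = CentroidSet.from_points([(10, 10), (30, 5)])
        stack = gaussian_stack(pts, (41, 41), radii=[9])
        direct = gaussian_mask(pts, 9, 3, (41, 41))
        assert np.array_equal(stack.masks[0], direct)

    def test_distant_points_are_disjoint_kernel_sums(self):
        p1 = CentroidSet.from_points([(10, 10)])
        p2 = CentroidSet.from_points([(50, 50)])
        both = CentroidSet.from_points([(10, 10), (50, 50)])
        stack = gaussian_stack(both, (61, 61))
        expected = gaussian_stack(p1, (61, 61)).masks + gaussian_stack(p2, (61, 61)).masks
        assert np.allclose(stack.masks, expected)

    def test_empty_radii_rejected(self):
        with pytest.raises(ValueError):
            gaussian_stack(CentroidSet.from_points([(1, 1)]), (4, 4), radii=[])


# -------------------------------------------------------- voronoi / distance
def _brute_force_nearest(points: np.ndarray, ids: np.ndarray, shape):
    """Independent per-pixel nearest-point scan (lowest id wins ties)."""
    out = np.zeros(shape, dtype=np.int64)
    dist = np.zeros(shape)
    for r in range(shape[0]):
        for c in range(shape[1]):
            best_d, best_id = np.inf, None
            for pid, (pr, pc) in zip(ids, points):
                d = np.hypot(r - pr, c - pc)
                if d < best_d - 1e-12:
                    best_d, best_id = d, pid
            out[r, c] = best_id
            dist[r, c] = best_d
    return out, dist


class TestVoronoiPartition:
    def test_matches_brute_force_on_random_points(self, rng):
        shape = (64, 64)
        pts = rng.uniform(0, 63, size=(5, 2))
        cset = CentroidSet.from_points(pts)
        expected, _ = _brute_force_nearest(cset.points, cset.ids, shape)
        assert np.array_equal(voronoi_partition(cset, shape), expected)

    def test_two_points_halfplane(self):
        cset = CentroidSet.from_points([(0, 0), (0, 10)])
        part = voronoi_partition(cset, (3, 11))
        assert part[0, 3] == 1
        assert part[0, 8] == 2

    def test_single_point_one_region(self):
        part = voronoi_partition(CentroidSet.from_points([(5, 5)]), (12, 12))
        assert np.all(part == 1)

    def test_regions_cover_and_are_connected(self, five_points):
        from skimage.measure import label as cc_label

        part = voronoi_partition(five_points, (64, 64))
        assert set(np.unique(part)) == set(five_points.ids)
        for pid in five_points.ids:
            comp = cc_label(part == pid, connectivity=2)
            assert comp.max() == 1  # Voronoi cells are connected

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            voronoi_partition(CentroidSet.empty(), (8, 8))


class TestDistanceTransform:
    def test_zero_at_points(self, five_points):
        d = distance_transform(five_points, (64, 64))
        for _, (r, c) in five_points:
            assert d[int(r), int(c)] == 0.0

    def test_three_four_five_triangle(self):
        d = distance_transform(CentroidSet.from_points([(0, 0)]), (8, 8))
        assert d[3, 4] == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        pts = CentroidSet.from_points(rng.uniform(0, 31, size=(4, 2)))
        # EDT measures to the rounded seed pixels, as annotations are pixels
        rounded = CentroidSet.from_points(pts.rounded())
        _, expected = _brute_force_nearest(rounded.points, rounded.ids, (32, 32))
        assert np.allclose(distance_transform(pts, (32, 32)), expected, atol=1e-9)


# -------------------------------------------------------------- voronoi label
class TestVoronoiLabel:
    def test_single_point_no_ridges(self):
        lab = voronoi_label(CentroidSet.from_points([(10, 10)]), (21, 21))
        assert (lab == BACKGROUND).sum() == 0
        fg = np.argwhere(lab == FOREGROUND)
        assert len(fg) > 0
        assert np.all(np.hypot(fg[:, 0] - 10, fg[:, 1] - 10) <= 2.5)
        assert (lab == IGNORED).sum() == 21 * 21 - len(fg)

    def test_two_point_ridge_is_perpendicular_bisector(self):
        cset = CentroidSet.from_points([(16, 8), (16, 24)])
        lab = voronoi_label(cset, (33, 33))
        ridge = np.argwhere(lab == BACKGROUND)
        # analytic bisector: col = 16; 4-neighbourhood test yields a 2-px band
        assert len(ridge) > 0
        assert np.all(np.abs(ridge[:, 1] - 16) <= 1.0)

    def test_annotated_points_are_foreground(self, five_points):
        lab = voronoi_label(five_points, (64, 64))
        for _, (r, c) in five_points:
            assert lab[int(r), int(c)] == FOREGROUND

    def test_values_are_ternary(self, five_points):
        lab = voronoi_label(five_points, (64, 64))
        assert set(np.unique(lab)) <= {0, 1, 2}

    def test_ridges_separate_all_region_pairs(self, five_points):
        part = voronoi_partition(five_points, (64, 64))
        ridges = voronoi_ridges(part)
        from skimage.measure import label as cc_label

        # removing ridge pixels disconnects the plane into the 5 cells
        open_regions = cc_label(~ridges, connectivity=1)
        assert open_regions.max() == len(five_points)


# -------------------------------------------------------------- cluster label
class TestClusterLabel:
    def test_points_overwhelmingly_foreground(self, small_scene):
        lab = initial_cluster_label(small_scene.image, small_scene.points)
        hits = [
            lab[int(r), int(c)] == FOREGROUND for _, (r, c) in small_scene.points
        ]
        assert np.mean(hits) >= 0.9

    def test_constant_image_degenerate(self, five_points):
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        with pytest.warns(UserWarning, match="constant"):
            lab = initial_cluster_label(img, five_points)
        assert np.all(lab == IGNORED)

    def test_values_are_ternary(self, small_scene):
        lab = initial_cluster_label(small_scene.image, small_scene.points)
        assert set(np.unique(lab)) <= {0, 1, 2}

    def test_shape_mismatch_rejected(self, small_scene):
        with pytest.raises(ValueError):
            initial_cluster_label(
                small_scene.image, small_scene.points, np.zeros((3, 3))
            )
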