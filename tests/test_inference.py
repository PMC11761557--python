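"""Inference pipeline: tiling arithmetic, Gaussian-map fusion rules,
centroid extraction thresholds, and the instance-refinement loop's
behavioural contract."""

import numpy as np
import pytest

from pointseg.core import CentroidSet, ModelOutput
from pointseg.inference import (
    InferenceConfig,
    extract_centroids,
    fuse_gaussian_maps,
    label_segmentation,
    refine_instances,
    run_inference,
    tile_predict,
)


class ConstantModel:
    """Stub emitting constant maps; records requested patch shapes."""

    def __init__(self, seg_value=0.0, k=2, gauss_value=0.0):
        self.seg_value = seg_value
        self.gauss_value = gauss_value
        self.n_gauss_branches = k
        self.calls = []

    def predict(self, image):
        h, w = image.shape[:2]
        self.calls.append((h, w))
        return ModelOutput(
            seg_prob=np.full((h, w), self.seg_value),
            gauss_maps=np.full((self.n_gauss_branches, h, w), self.gauss_value),
        )


class TestTilePredict:
    def test_exact_patch_is_single_forward(self):
        model = ConstantModel(seg_value=0.7)
        cfg = InferenceConfig(patch_size=32, overlap=8)
        out = tile_predict(model, np.zeros((32, 32, 3), np.uint8), cfg)
        assert model.calls == [(32, 32)]
        assert np.allclose(out.seg_prob, 0.7)

    def test_constant_model_stitches_exactly(self):
        model = ConstantModel(seg_value=0.3, gauss_value=0.6)
        cfg = InferenceConfig(patch_size=32, overlap=8)
        out = tile_predict(model, np.zeros((70, 90, 3), np.uint8), cfg)
        assert out.seg_prob.shape == (70, 90)
        assert np.allclose(out.seg_prob, 0.3)
        assert np.allclose(out.gauss_maps, 0.6)

    def test_output_matches_input_size(self):
        model = ConstantModel()
        cfg = InferenceConfig(patch_size=64, overlap=16)
        out = tile_predict(model, np.zeros((150, 111, 3), np.uint8), cfg)
        assert out.seg_prob.shape == (150, 111)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            InferenceConfig(patch_size=32, overlap=40)


class TestFusion:
    def test_majority_rule_k4(self):
        maps = np.zeros((4, 1, 1))
        maps[:2, 0, 0] = 0.9  # 2 of 4 branches vote foreground
        assert fuse_gaussian_maps(maps)[0, 0]
        maps2 = np.zeros((4, 1, 1))
        maps2[0, 0, 0] = 0.9  # only 1 vote
        assert not fuse_gaussian_maps(maps2)[0, 0]

    def test_k1_equals_thresholding(self, rng):
        m = rng.random((1, 8, 8))
        assert np.array_equal(fuse_gaussian_maps(m, 0.5), m[0] >= 0.5)

    def test_odd_k_needs_strict_majority(self):
        maps = np.zeros((3, 1, 1))
        maps[0, 0, 0] = 1.0
        assert not fuse_gaussian_maps(maps)[0, 0]  # 1 < ceil(3/2) = 2
        maps[1, 0, 0] = 1.0
        assert fuse_gaussian_maps(maps)[0, 0]


class TestCentroids:
    def test_area_threshold_boundary(self):
        fg = np.zeros((32, 32), bool)
        fg[2:6, 2:7] = True          # 20 px -> kept ("fewer than 20" removed)
        fg[20:21, 20:39 - 20] = True  # small sliver
        c20 = extract_centroids(fg, min_area=20)
        assert len(c20) == 1
        fg19 = np.zeros((32, 32), bool)
        fg19[2:6, 2:7] = True
        fg19[5, 6] = False            # 19 px -> removed
        assert len(extract_centroids(fg19, min_area=20)) == 0

    def test_square_centroid(self):
        fg = np.zeros((32, 32), bool)
        fg[10:15, 10:15] = True
        cset = extract_centroids(fg, min_area=20)
        assert np.allclose(cset.points, [[12, 12]])

    def test_empty_map(self):
        assert len(extract_centroids(np.zeros((8, 8), bool))) == 0


class TestLabelSegmentation:
    def test_all_background(self):
        assert label_segmentation(np.zeros((8, 8))).max() == 0

    def test_two_blobs(self):
        p = np.zeros((16, 16))
        p[2:5, 2:5] = 1.0
        p[10:13, 10:13] = 1.0
        assert label_segmentation(p).max() == 2

    def test_diagonal_touch_shares_label(self):
        p = np.zeros((6, 6))
        p[1, 1] = p[2, 2] = 1.0  # 8-connectivity joins diagonals
        assert label_segmentation(p).max() == 1


def _square_instance(shape, r0, c0, size, label=1):
    S = np.zeros(shape, dtype=np.int32)
    S[r0 : r0 + size, c0 : c0 + size] = label
    return S


class TestRefineInstances:
    CFG = InferenceConfig(patch_size=64, overlap=16, min_center_area=5)

    def test_instance_without_centroid_gains_one(self):
        S = _square_instance((32, 32), 5, 5, 10)
        I, C = refine_instances(S, CentroidSet.empty(), self.CFG)
        assert I.max() == 1
        assert len(C) == 1
        r, c = C.rounded()[0]
        assert S[r, c] == 1
        assert np.array_equal(I > 0, S > 0)

    def test_background_centroid_discarded(self):
        S = _square_instance((32, 32), 5, 5, 10)
        C = CentroidSet.from_points([(9, 9), (25, 25)])  # second is background
        I, C_final = refine_instances(S, C, self.CFG)
        assert I.max() == 1
        assert len(C_final) == 1
        assert np.array_equal(C_final.rounded()[0], [9, 9])

    def test_small_subregion_merged_and_centroid_removed(self):
        # 10x10 instance (100 px); two centroids placed so the Voronoi split
        # leaves one sub-region of 8 px < 10% of 100
        S = _square_instance((40, 40), 10, 10, 10)
        C = CentroidSet.from_points([(15, 14), (15, 36)])
        I, C_final = refine_instances(S, C, self.CFG)
        assert I.max() == 1          # merged back into one instance
        assert len(C_final) == 1     # surplus centroid removed
        assert np.array_equal(I > 0, S > 0)

    def test_two_centroids_split_one_component(self):
        S = np.zeros((30, 50), dtype=np.int32)
        S[10:20, 5:45] = 1  # one wide component
        C = CentroidSet.from_points([(15, 14), (15, 36)])
        I, C_final = refine_instances(S, C, self.CFG)
        assert I.max() == 2
        assert len(C_final) == 2
        assert np.array_equal(I > 0, S > 0)

    def test_every_final_instance_holds_exactly_one_centroid(self, rng):
        # adversarial random blobs and centroids
        from skimage.measure import label as cc_label

        fg = rng.random((48, 48)) > 0.72
        S = cc_label(fg, connectivity=2).astype(np.int32)
        pts = rng.integers(0, 48, size=(10, 2)).astype(float)
        I, C_final = refine_instances(S, CentroidSet.from_points(pts), self.CFG)
        assert np.array_equal(I > 0, S > 0)  # foreground never altered
        owners = [I[r, c] for r, c in C_final.rounded()]
        ids = sorted(set(np.unique(I)) - {0})
        assert sorted(owners) == ids

    def test_empty_segmentation(self):
        I, C = refine_instances(np.zeros((8, 8), np.int32), CentroidSet.empty(), self.CFG)
        assert I.max() == 0 and len(C) == 0


class TestRunInference:
    def test_blank_constant_zero_model(self):
        model = ConstantModel(seg_value=0.0, k=2)
        cfg = InferenceConfig(patch_size=32, overlap=8)
        I, C = run_inference(model, np.zeros((32, 32, 3), np.uint8), cfg)
        assert I.max() == 0 and len(C) == 0

    def test_oracle_separates_touching_pair(self, small_scene):
        """GT mask + GT centers: the touching pair is one connected
        component but two refined instances."""
        from pointseg.experiments import OracleModel
        from skimage.measure import label as cc_label

        model = OracleModel(small_scene, radii=(5, 7, 9, 11))
        cfg = InferenceConfig(patch_size=64, overlap=16, min_center_area=5)
        coarse_cc = cc_label(small_scene.gt_instances > 0, connectivity=2)
        I, C = run_inference(model, small_scene.image, cfg)
        n_gt = small_scene.gt_instances.max()
        assert coarse_cc.max() < n_gt     # touching pair merged
        assert I.max() == n_gt            # refinement separates it
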