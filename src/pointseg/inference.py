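"""Test-time pipeline: tiled prediction, Gaussian-map fusion, centroid
extraction, and Voronoi-based instance refinement.

The refinement loop turns a semantic segmentation map ``S`` and a set
of predicted center points ``C`` into an instance map in which every
instance holds exactly one centroid: instances without a centroid get
one added at an interior point (a missed center prediction), centroids
on background are dropped (false positives), the Voronoi partition of
the surviving centroids splits each connected component, and split
pieces smaller than 10% of their instance are merged back into their
largest neighbouring piece. The foreground pixel set is never altered —
refinement only re-partitions it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label, regionprops

from .core import CentroidSet, ModelOutput, compact_instances
from .pseudolabels import voronoi_partition


@dataclass(frozen=True)
class InferenceConfig:
    patch_size: int = 224
    overlap: int = 80
    fg_threshold: float = 0.5
    min_center_area: int = 20
    merge_fraction: float = 0.10
    max_refine_iters: int = 10

    def __post_init__(self):
        if not 0 <= self.overlap < self.patch_size:
            raise ValueError("overlap must satisfy 0 <= overlap < patch_size")
        if not 0.0 < self.fg_threshold < 1.0:
            raise ValueError("fg_threshold must lie in (0, 1)")
        if not 0.0 < self.merge_fraction < 1.0:
            raise ValueError("merge_fraction must lie in (0, 1)")


def tile_predict(model, image: np.ndarray, config: InferenceConfig = InferenceConfig()) -> ModelOutput:
    """Predict a full image by averaging overlapping patch predictions.

    Patches of ``patch_size`` are slid with stride ``patch_size -
    overlap``; per-pixel results are arithmetic means over every patch
    covering the pixel. Images smaller than a patch are predicted
    directly.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    ps = config.patch_size
    if h <= ps and w <= ps:
        return model.predict(image)
    stride = ps - config.overlap
    starts_r = _tile_starts(h, ps, stride)
    starts_c = _tile_starts(w, ps, stride)
    k = getattr(model, "n_gauss_branches", 0)
    seg_acc = np.zeros((h, w))
    gauss_acc = np.zeros((k, h, w))
    counts = np.zeros((h, w))
    for r0 in starts_r:
        for c0 in starts_c:
            r1, c1 = min(r0 + ps, h), min(c0 + ps, w)
            out = model.predict(image[r0:r1, c0:c1])
            seg_acc[r0:r1, c0:c1] += out.seg_prob
            if k:
                gauss_acc[:, r0:r1, c0:c1] += out.gauss_maps
            counts[r0:r1, c0:c1] += 1
    seg = seg_acc / counts
    gauss = gauss_acc / counts if k else np.empty((0, h, w))
    return ModelOutput(seg_prob=seg, gauss_maps=gauss)


def _tile_starts(extent: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, max(extent - patch, 0) + 1, stride))
    if starts[-1] + patch < extent:
        starts.append(extent - patch)
    return starts


def fuse_gaussian_maps(gauss_maps: np.ndarray, fg_threshold: float = 0.5) -> np.ndarray:
    """Majority vote over branches: a pixel is center-foreground iff at
    least ceil(k/2) branches predict a value >= the threshold."""
    gauss_maps = np.atleast_3d(np.asarray(gauss_maps))
    k = gauss_maps.shape[0]
    if k < 1:
        raise ValueError("need at least one Gaussian map")
    votes = (gauss_maps >= fg_threshold).sum(axis=0)
    return votes >= -(-k // 2)


def extract_centroids(center_fg: np.ndarray, min_area: int = 20) -> CentroidSet:
    """Centroids of the fused map's connected components, discarding
    noise components with area strictly below ``min_area``."""
    comps = cc_label(np.asarray(center_fg).astype(bool), connectivity=2)
    pts = []
    for region in regionprops(comps):
        if region.area >= min_area:
            pts.append(np.rint(region.centroid))
    if not pts:
        return CentroidSet.empty()
    return CentroidSet.from_points(np.array(pts))


def label_segmentation(seg_prob: np.ndarray, fg_threshold: float = 0.5) -> np.ndarray:
    """Threshold and 8-connected-component label the segmentation map."""
    fg = np.asarray(seg_prob) >= fg_threshold
    return cc_label(fg, connectivity=2).astype(np.int32)


def _interior_point(mask: np.ndarray) -> np.ndarray:
    """A representative point guaranteed inside the mask: the centroid if
    it falls inside, otherwise the interior pixel farthest from the
    boundary (pole of inaccessibility)."""
    rows, cols = np.nonzero(mask)
    centroid = np.rint([rows.mean(), cols.mean()]).astype(int)
    if (
        0 <= centroid[0] < mask.shape[0]
        and 0 <= centroid[1] < mask.shape[1]
        and mask[centroid[0], centroid[1]]
    ):
        return centroid.astype(float)
    dist = ndi.distance_transform_edt(mask)
    best = np.unravel_index(np.argmax(dist), mask.shape)
    return np.array(best, dtype=float)


def _split_by_partition(S: np.ndarray, partition: np.ndarray, merge_fraction: float):
    """Split every instance of S by the Voronoi partition; merge pieces
    below ``merge_fraction`` of their instance's area into their largest
    neighbouring piece of the same instance. Returns (instance map I,
    set of surviving partition cell ids)."""
    I = np.zeros_like(S, dtype=np.int32)
    surviving_cells: set[int] = set()
    next_label = 1
    struct = ndi.generate_binary_structure(2, 2)
    for inst_id in np.unique(S):
        if inst_id == 0:
            continue
        inst_mask = S == inst_id
        area = int(inst_mask.sum())
        pieces = {}
        for cell in np.unique(partition[inst_mask]):
            piece = inst_mask & (partition == cell)
            # a cell may cut an instance into several components; keep them
            comp = cc_label(piece, connectivity=2)
            for c in range(1, comp.max() + 1):
                pieces[len(pieces)] = {"mask": comp == c, "cell": int(cell)}
        # merge small pieces into their largest neighbour within the instance
        changed = True
        while changed and len(pieces) > 1:
            changed = False
            small = [
                pid
                for pid, p in pieces.items()
                if p["mask"].sum() < merge_fraction * area
            ]
            if not small:
                break
            pid = min(small, key=lambda q: pieces[q]["mask"].sum())
            grown = ndi.binary_dilation(pieces[pid]["mask"], struct)
            neighbours = [
                q for q, p in pieces.items() if q != pid and (grown & p["mask"]).any()
            ]
            if neighbours:
                target = max(neighbours, key=lambda q: pieces[q]["mask"].sum())
                pieces[target]["mask"] = pieces[target]["mask"] | pieces[pid]["mask"]
                del pieces[pid]
                changed = True
        for p in pieces.values():
            I[p["mask"]] = next_label
            surviving_cells.add(p["cell"])
            next_label += 1
    return I, surviving_cells


def refine_instances(
    S: np.ndarray,
    C: CentroidSet,
    config: InferenceConfig = InferenceConfig(),
) -> tuple[np.ndarray, CentroidSet]:
    """Instance-refinement loop aligning centroids with instances.

    Iterates (a) add a centroid at an interior point of every instance
    of S lacking one, (b) discard centroids on background, (c) split
    instances by the Voronoi partition of the centroids and merge
    sub-regions below ``merge_fraction`` of the instance area, (d) drop
    centroids whose sub-region was merged away — until every final
    instance holds exactly one centroid or ``max_refine_iters`` passes.
    """
    S = np.asarray(S, dtype=np.int32)
    if not (S > 0).any():
        return np.zeros_like(S), CentroidSet.empty()
    points = [tuple(p) for p in C.rounded()] if len(C) else []

    I = None
    for _ in range(config.max_refine_iters):
        # (b) drop centroids on background of S
        points = [p for p in points if S[p[0], p[1]] > 0]
        # (a) every instance of S needs at least one centroid
        covered = {S[p[0], p[1]] for p in points}
        for inst_id in np.unique(S):
            if inst_id > 0 and inst_id not in covered:
                ip = _interior_point(S == inst_id)
                points.append((int(ip[0]), int(ip[1])))
        cset = CentroidSet.from_points(np.array(points, dtype=float))
        partition = voronoi_partition(cset, S.shape)
        # (c) split by Voronoi cells, merging small pieces
        I, surviving = _split_by_partition(S, partition, config.merge_fraction)
        # (d) remove centroids whose cell no longer owns any sub-region
        kept = [p for i, p in enumerate(points) if int(cset.ids[i]) in surviving]
        converged = len(kept) == len(points) and _one_centroid_per_instance(I, kept)
        points = kept
        if converged:
            break
    else:
        if not _one_centroid_per_instance(I, points):
            warnings.warn("instance refinement did not converge; returning last state")

    # final guarantee: every instance holds exactly one centroid
    final_points = _finalise_centroids(I, points)
    return compact_instances(I), final_points


def _one_centroid_per_instance(I: np.ndarray, points) -> bool:
    owners = [I[p[0], p[1]] for p in points]
    ids = set(np.unique(I)) - {0}
    return sorted(owners) == sorted(ids) and len(set(owners)) == len(owners)


def _finalise_centroids(I: np.ndarray, points) -> CentroidSet:
    by_instance: dict[int, tuple[int, int]] = {}
    for p in points:
        inst = int(I[p[0], p[1]])
        if inst > 0 and inst not in by_instance:
            by_instance[inst] = p
    out = []
    for inst_id in sorted(set(np.unique(I)) - {0}):
        if inst_id in by_instance:
            out.append(by_instance[inst_id])
        else:
            ip = _interior_point(I == inst_id)
            out.append((int(ip[0]), int(ip[1])))
    if not out:
        return CentroidSet.empty()
    return CentroidSet.from_points(np.array(out, dtype=float))


def run_inference(
    model,
    image: np.ndarray,
    config: InferenceConfig = InferenceConfig(),
    coarse: bool = False,
) -> tuple[np.ndarray, CentroidSet]:
    """Full pipeline: tiled prediction -> Gaussian fusion -> centroids ->
    connected components -> instance refinement.

    With ``coarse=True`` the Algorithm-style refinement is skipped and
    the instance map is the plain Voronoi split of the segmentation
    components (or the components themselves when the model has no
    Gaussian branches).
    """
    out = tile_predict(model, image, config)
    S = label_segmentation(out.seg_prob, config.fg_threshold)
    if out.n_gauss_branches == 0:
        return compact_instances(S), CentroidSet.empty()
    center_fg = fuse_gaussian_maps(out.gauss_maps, config.fg_threshold)
    C = extract_centroids(center_fg, config.min_center_area)
    if coarse:
        if len(C) == 0:
            return compact_instances(S), C
        partition = voronoi_partition(C, S.shape)
        I, _ = _split_by_partition(S, partition, merge_fraction=1e-12)
        return compact_instances(I), C
    return refine_instances(S, C, config)
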