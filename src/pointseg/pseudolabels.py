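"""Training targets derived from point annotations alone.

Four kinds of supervision are synthesised from the (row, col) nucleus
centers:

* multi-scale **Gaussian masks** — per-branch center-point regression
  targets, value ``exp(-d^2 / (2 sigma^2))`` within radius ``r`` of the
  nearest point and 0 beyond it, one map per radius with ``sigma = r/3``;
* the **Voronoi label** — a ternary mask whose background class traces
  the ridges of the Voronoi partition of the points (encoding separation
  between adjacent nuclei) and whose foreground class is a small disk
  around each point, everything else ignored;
* the **cluster label** — a ternary mask from 3-way k-means over
  per-pixel colour + distance features;
* the **distance map** — Euclidean distance to the nearest annotated
  point, also a feature channel for the clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.cluster import KMeans
from skimage.morphology import disk

from .core import BACKGROUND, FOREGROUND, IGNORED, CentroidSet

DEFAULT_RADII = (7, 9, 11, 13)
DISTANCE_CLIP = 20.0  # px; distances beyond this are equally "far"


@dataclass(frozen=True)
class GaussianMaskStack:
    """k per-branch regression targets in [0, 1], one per kernel radius."""

    masks: np.ndarray          # (k, H, W)
    radii: tuple[float, ...]
    bandwidths: tuple[float, ...]

    def __post_init__(self):
        if self.masks.ndim != 3 or self.masks.shape[0] != len(self.radii):
            raise ValueError("masks must be (k, H, W) with one mask per radius")


def _point_seed_mask(points: CentroidSet, shape) -> np.ndarray:
    seeds = np.zeros(shape, dtype=bool)
    if len(points):
        points.validate_within(shape)
        rc = points.rounded()
        seeds[rc[:, 0], rc[:, 1]] = True
    return seeds


def distance_transform(points: CentroidSet, shape) -> np.ndarray:
    """Euclidean distance from every pixel to the nearest annotated point."""
    if len(points) == 0:
        raise ValueError("distance transform needs at least one point")
    return ndi.distance_transform_edt(~_point_seed_mask(points, shape))


def gaussian_mask(points: CentroidSet, radius: float, sigma: float, shape) -> np.ndarray:
    """Single-branch Gaussian center-point target.

    Value 1 at each annotated point, decaying as ``exp(-d^2/(2 sigma^2))``
    with distance ``d`` to the nearest point, hard-zeroed where
    ``d >= radius``. An empty point set yields an all-zero map.
    """
    if radius <= 0 or sigma <= 0:
        raise ValueError("radius and sigma must be positive")
    if len(points) == 0:
        return np.zeros(shape, dtype=np.float64)
    d = distance_transform(points, shape)
    mask = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    mask[d >= radius] = 0.0
    return mask


def gaussian_stack(
    points: CentroidSet, shape, radii=DEFAULT_RADII
) -> GaussianMaskStack:
    """One Gaussian mask per radius with bandwidth ``sigma_i = r_i / 3``."""
    radii = tuple(float(r) for r in radii)
    if not radii:
        raise ValueError("radii must be nonempty")
    bandwidths = tuple(r / 3.0 for r in radii)
    masks = np.stack(
        [gaussian_mask(points, r, s, shape) for r, s in zip(radii, bandwidths)]
    )
    return GaussianMaskStack(masks=masks, radii=radii, bandwidths=bandwidths)


def voronoi_partition(points: CentroidSet, shape) -> np.ndarray:
    """Label every pixel with the id of its nearest point (Euclidean).

    Ties are broken in favour of the lowest point id, making the
    partition deterministic.
    """
    if len(points) == 0:
        raise ValueError("voronoi partition needs at least one point")
    points.validate_within(shape)
    h, w = shape
    pts = points.points  # (n, 2), ordered by position in the set
    ids = points.ids
    out = np.empty((h, w), dtype=np.int64)
    cols = np.arange(w)
    # row-chunked brute force keeps memory bounded on large tiles while
    # preserving exact lowest-id tie-breaking (argmin returns the first hit)
    chunk = max(1, int(2e6) // max(1, len(pts)) // w + 1)
    for r0 in range(0, h, chunk):
        r1 = min(h, r0 + chunk)
        rows = np.arange(r0, r1)
        d2 = (rows[:, None, None] - pts[None, None, :, 0]) ** 2 + (
            cols[None, :, None] - pts[None, None, :, 1]
        ) ** 2
        out[r0:r1] = ids[np.argmin(d2, axis=2)]
    return out


def voronoi_ridges(partition: np.ndarray) -> np.ndarray:
    """Pixels whose 4-neighbourhood spans >= 2 Voronoi regions."""
    ridge = np.zeros(partition.shape, dtype=bool)
    ridge[:-1, :] |= partition[:-1, :] != partition[1:, :]
    ridge[1:, :] |= partition[1:, :] != partition[:-1, :]
    ridge[:, :-1] |= partition[:, :-1] != partition[:, 1:]
    ridge[:, 1:] |= partition[:, 1:] != partition[:, :-1]
    return ridge


def voronoi_label(
    points: CentroidSet, shape, point_radius: int = 2
) -> np.ndarray:
    """Ternary Voronoi supervision: ridges -> background, dilated points ->
    foreground, everything else ignored. On the rare collision of the two
    sets the ridge (background) wins."""
    partition = voronoi_partition(points, shape)
    label = np.full(shape, IGNORED, dtype=np.uint8)
    fg = ndi.binary_dilation(_point_seed_mask(points, shape), disk(point_radius))
    label[fg] = FOREGROUND
    label[voronoi_ridges(partition)] = BACKGROUND
    return label


def _cluster_to_ternary(
    assignments: np.ndarray,
    point_rc: np.ndarray,
    distance_feature: np.ndarray,
    n_clusters: int,
) -> np.ndarray:
    """Map k-means clusters to {fg, bg, ignored}: the cluster holding the
    annotated points becomes foreground, the remaining cluster with the
    largest mean distance-to-point becomes background, the rest ignored."""
    label = np.full(assignments.shape, IGNORED, dtype=np.uint8)
    votes = np.bincount(assignments[point_rc[:, 0], point_rc[:, 1]], minlength=n_clusters)
    fg_cluster = int(np.argmax(votes))
    label[assignments == fg_cluster] = FOREGROUND
    rest = [c for c in range(n_clusters) if c != fg_cluster]
    mean_dist = [distance_feature[assignments == c].mean() if (assignments == c).any() else -1
                 for c in rest]
    bg_cluster = rest[int(np.argmax(mean_dist))]
    label[assignments == bg_cluster] = BACKGROUND
    return label


def initial_cluster_label(
    image: np.ndarray,
    points: CentroidSet,
    distance_map: np.ndarray | None = None,
    n_clusters: int = 3,
    random_state: int = 0,
) -> np.ndarray:
    """Ternary cluster label from 3-way k-means on (R, G, B, clipped
    distance), all features scaled to [0, 1].

    A constant-colour image is degenerate: a warning is issued and the
    whole label is marked ignored.
    """
    image = np.asarray(image, dtype=np.float64)
    shape = image.shape[:2]
    if distance_map is None:
        distance_map = distance_transform(points, shape)
    if distance_map.shape != shape:
        raise ValueError("image and distance map shapes disagree")
    if image.std() < 1e-6:
        warnings.warn("constant image: cluster label degenerate, all pixels ignored")
        return np.full(shape, IGNORED, dtype=np.uint8)
    features = _cluster_features(image, distance_map)
    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=random_state)
    assignments = km.fit_predict(features).reshape(shape)
    return _cluster_to_ternary(
        assignments, points.rounded(), features[:, 3].reshape(shape), n_clusters
    )


def _cluster_features(image: np.ndarray, distance_map: np.ndarray) -> np.ndarray:
    rgb = image.reshape(-1, 3) / 255.0
    d = np.clip(distance_map, 0, DISTANCE_CLIP).reshape(-1, 1) / DISTANCE_CLIP
    return np.column_stack([rgb, d])


def make_all_labels(image, points, radii=DEFAULT_RADII):
    """Convenience: every pseudo-label needed to train on one image."""
    shape = np.asarray(image).shape[:2]
    dist = distance_transform(points, shape)
    return {
        "gauss": gaussian_stack(points, shape, radii),
        "voronoi": voronoi_label(points, shape),
        "cluster": initial_cluster_label(image, points, dist),
        "distance": dist,
    }
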