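"""Synthetic H&E-like nuclei scenes with exact ground truth.

Generates image tiles that mimic hematoxylin-and-eosin stained tissue at
the level the rest of the pipeline cares about: purple-ish elliptical
nuclei on a pink-ish background with per-pixel stain variation, optional
elongated nuclei, and deliberately touching nucleus pairs (boundary gap
<= 2 px) that exercise the instance-separation machinery. Every scene
comes with an exact instance-label map and one (optionally jittered)
center-point annotation per nucleus, so all downstream stages are
testable without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .core import CentroidSet

# Rough H&E palette: hematoxylin nuclei vs eosin background (RGB means).
DEFAULT_NUCLEUS_RGB = (110.0, 70.0, 165.0)
DEFAULT_BACKGROUND_RGB = (232.0, 185.0, 205.0)


@dataclass(frozen=True)
class StainParams:
    """Per-channel mean/sd of the two-tone stain rendering."""

    nucleus_rgb: tuple[float, float, float] = DEFAULT_NUCLEUS_RGB
    background_rgb: tuple[float, float, float] = DEFAULT_BACKGROUND_RGB
    color_sd: float = 12.0       # per-nucleus colour variation
    pixel_noise_sd: float = 6.0  # i.i.d. pixel noise after smoothing
    texture_sd: float = 18.0     # low-frequency eosin/stroma colour texture
    texture_scale: float = 6.0   # correlation length of the texture, px
    smooth_sigma: float = 0.8


@dataclass(frozen=True)
class SceneConfig:
    height: int = 128
    width: int = 128
    n_nuclei: int = 12
    radius_range: tuple[int, int] = (4, 9)
    elongation_prob: float = 0.3
    touching_pairs: int = 2
    point_jitter_sd: float = 1.0
    stain_params: StainParams = field(default_factory=StainParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei < 1:
            raise ValueError(f"n_nuclei must be >= 1, got {self.n_nuclei}")
        rmin, rmax = self.radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if 2 * rmax >= min(self.height, self.width):
            raise ValueError(
                f"radius_range {self.radius_range} does not fit a "
                f"{self.height}x{self.width} image"
            )
        if self.point_jitter_sd < 0:
            raise ValueError("point_jitter_sd must be >= 0")
        if not 0.0 <= self.elongation_prob <= 1.0:
            raise ValueError("elongation_prob must lie in [0, 1]")
        if self.touching_pairs < 0 or 2 * self.touching_pairs > self.n_nuclei:
            raise ValueError(
                f"touching_pairs={self.touching_pairs} incompatible with "
                f"n_nuclei={self.n_nuclei}"
            )


@dataclass
class Scene:
    """A rendered tile with exact ground truth.

    image : (H, W, 3) uint8 RGB; gt_instances : (H, W) int32 labels
    (0 background, 1..N nuclei); points : one centroid per instance,
    id i pointing into instance i.
    """

    image: np.ndarray
    gt_instances: np.ndarray
    points: CentroidSet
    config: SceneConfig


def _nucleus_mask(shape, center, radius, aspect, angle):
    """Boolean mask of one (possibly elongated) filled ellipse."""
    # keep area comparable across aspect ratios: semi-axes r*sqrt(a), r/sqrt(a)
    a = radius * np.sqrt(aspect)
    b = radius / np.sqrt(aspect)
    rr, cc = draw_ellipse(center[0], center[1], a, b, shape=shape, rotation=angle)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _sample_shape(rng, cfg: SceneConfig):
    rmin, rmax = cfg.radius_range
    radius = rng.uniform(rmin, rmax)
    elongated = rng.random() < cfg.elongation_prob
    # elongated nuclei mirror the hard case of slender, densely packed cells
    aspect = rng.uniform(2.0, 4.0) if elongated else rng.uniform(1.0, 1.3)
    angle = rng.uniform(0, np.pi)
    return radius, aspect, angle, elongated


def _place_free(rng, cfg, occupied, forbidden, max_tries=200):
    """Place one nucleus not overlapping `forbidden` (occupied dilated by the
    separation gap). Returns its mask or None."""
    shape = occupied.shape
    rmax = cfg.radius_range[1]
    for _ in range(max_tries):
        radius, aspect, angle, elong = _sample_shape(rng, cfg)
        margin = int(np.ceil(radius * np.sqrt(aspect))) + 1
        if shape[0] - margin <= margin or shape[1] - margin <= margin:
            continue
        center = (
            rng.integers(margin, shape[0] - margin),
            rng.integers(margin, shape[1] - margin),
        )
        mask = _nucleus_mask(shape, center, radius, aspect, angle)
        if mask.any() and not (mask & forbidden).any():
            return mask, elong
    return None


def _place_touching(rng, cfg, occupied, anchor_mask, max_tries=200):
    """Place a nucleus whose boundary lies within 2 px of `anchor_mask`
    without overlapping anything already occupied."""
    shape = occupied.shape
    # partner must become 8-adjacent to the anchor (boundary gap 0) so the
    # pair merges in a plain connected-component labelling
    touch_zone = ndi.binary_dilation(anchor_mask, ndi.generate_binary_structure(2, 2))
    rows, cols = np.nonzero(anchor_mask)
    a_center = np.array([rows.mean(), cols.mean()])
    for _ in range(max_tries):
        radius, aspect, angle, elong = _sample_shape(rng, cfg)
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(theta), np.cos(theta)])
        # march inward from a safely distant start until the masks touch
        start = 2 * cfg.radius_range[1] * np.sqrt(aspect) + 4
        for dist in np.arange(start, 2.0, -1.0):
            center = a_center + direction * dist
            ic = (int(round(center[0])), int(round(center[1])))
            if not (0 <= ic[0] < shape[0] and 0 <= ic[1] < shape[1]):
                continue
            mask = _nucleus_mask(shape, ic, radius, aspect, angle)
            if not mask.any() or (mask & occupied).any():
                break  # marched too far: overlap; try another draw
            if (mask & touch_zone).any():
                return mask, elong
    return None


def generate_scene(config: SceneConfig) -> Scene:
    """Render one synthetic scene. Deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    gt = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    struct = ndi.generate_binary_structure(2, 2)

    def forbidden():
        # 3-px separation gap around existing nuclei for non-touching placement
        return ndi.binary_dilation(occupied, struct, iterations=3)

    masks: list[np.ndarray] = []
    n_restarts = 8
    for _ in range(n_restarts):
        gt[:] = 0
        occupied[:] = False
        masks.clear()
        ok = True
        for _pair in range(cfg.touching_pairs):
            placed = _place_free(rng, cfg, occupied, forbidden())
            if placed is None:
                ok = False
                break
            anchor, _ = placed
            occupied |= anchor
            partner = _place_touching(rng, cfg, occupied, anchor)
            if partner is None:
                ok = False
                break
            masks.append(anchor)
            masks.append(partner[0])
            occupied |= partner[0]
        if not ok:
            continue
        for _ in range(cfg.n_nuclei - 2 * cfg.touching_pairs):
            placed = _place_free(rng, cfg, occupied, forbidden())
            if placed is None:
                ok = False
                break
            masks.append(placed[0])
            occupied |= placed[0]
        if ok:
            break
    else:
        raise RuntimeError(f"could not place nuclei after retries for config {cfg}")

    for label, mask in enumerate(masks, start=1):
        gt[mask] = label

    points = _annotate_points(rng, gt, cfg.point_jitter_sd)
    image = _render(rng, gt, cfg.stain_params)
    return Scene(image=image, gt_instances=gt, points=points, config=cfg)


def _annotate_points(rng, gt: np.ndarray, jitter_sd: float) -> CentroidSet:
    ids, pts = [], []
    for label in range(1, gt.max() + 1):
        mask = gt == label
        rows, cols = np.nonzero(mask)
        centroid = np.array([rows.mean(), cols.mean()])
        point = np.rint(centroid)
        if jitter_sd > 0:
            point = np.rint(centroid + rng.normal(0, jitter_sd, size=2))
        # keep the annotation inside its own instance
        in_bounds = 0 <= point[0] < gt.shape[0] and 0 <= point[1] < gt.shape[1]
        if not in_bounds or not mask[int(point[0]), int(point[1])]:
            inside = np.column_stack([rows, cols])
            nearest = np.argmin(((inside - point) ** 2).sum(axis=1))
            point = inside[nearest].astype(float)
        ids.append(label)
        pts.append(point)
    return CentroidSet(np.array(ids), np.array(pts))


def _render(rng, gt: np.ndarray, stain: StainParams) -> np.ndarray:
    h, w = gt.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    bg = np.array(stain.background_rgb)
    img[:] = bg + rng.normal(0, stain.color_sd / 2, size=(h, w, 3))
    if stain.texture_sd > 0:
        # smooth colour field mimicking eosin/stroma texture in the tissue
        field = ndi.gaussian_filter(
            rng.normal(0, 1, size=(h, w, 3)), (stain.texture_scale, stain.texture_scale, 0)
        )
        sd = field.std() or 1.0
        img += field * (stain.texture_sd / sd)
    for label in range(1, gt.max() + 1):
        color = np.array(stain.nucleus_rgb) + rng.normal(0, stain.color_sd, size=3)
        img[gt == label] = color
    if stain.smooth_sigma > 0:
        img = ndi.gaussian_filter(img, (stain.smooth_sigma, stain.smooth_sigma, 0))
    img += rng.normal(0, stain.pixel_noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def boundary_distance(gt: np.ndarray, id_a: int, id_b: int) -> float:
    """Minimum pixel gap between two instances' boundaries (0 = adjacent)."""
    a = gt == id_a
    if not a.any() or not (gt == id_b).any():
        return np.inf
    dist = ndi.distance_transform_edt(~a)
    return float(dist[gt == id_b].min()) - 1.0


def touching_pair_count(gt: np.ndarray, gap: float = 2.0) -> int:
    """Number of instance pairs whose boundary distance is <= gap px."""
    ids = np.unique(gt)
    ids = ids[ids > 0]
    count = 0
    for i, a in enumerate(ids):
        dist = ndi.distance_transform_edt(gt != a)
        for b in ids[i + 1:]:
            if float(dist[gt == b].min()) - 1.0 <= gap:
                count += 1
    return count


def scene_to_disk(scene: Scene, directory, stem: str = "scene") -> dict:
    """Write image PNG, 16-bit instance PNG and a points CSV.

    Round-trips losslessly through :mod:`pointseg.io_formats`.
    """
    from . import io_formats
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{stem}.png",
        "instances": directory / f"{stem}_label.png",
        "points": directory / f"{stem}_points.csv",
    }
    if scene.gt_instances.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for a 16-bit label image")
    io_formats.write_image(scene.image, paths["image"])
    io_formats.write_instance_map(scene.gt_instances, paths["instances"])
    io_formats.write_points(scene.points, paths["points"])
    return paths
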