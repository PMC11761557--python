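"""Shared domain containers.

Conventions used throughout the package (and enforced by the I/O tests):
coordinates are 0-based ``(row, col)`` pairs with the row axis pointing
down; instance maps are integer images where 0 is background and
instances carry ids 1..N; ternary pseudo-labels take values
0 = background, 1 = foreground, 2 = ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKGROUND = 0
FOREGROUND = 1
IGNORED = 2

TERNARY_VALUES = frozenset({BACKGROUND, FOREGROUND, IGNORED})


@dataclass(frozen=True)
class CentroidSet:
    """An ordered set of nucleus center points with stable integer ids.

    Parameters
    ----------
    ids : (n,) int array of unique ids.
    points : (n, 2) float or int array of (row, col) coordinates.
    """

    ids: np.ndarray
    points: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.ids, dtype=np.int64)
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if ids.shape[0] != pts.shape[0]:
            raise ValueError("ids and points must have the same length")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("centroid ids must be unique")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return zip(self.ids.tolist(), map(tuple, self.points.tolist()))

    def rounded(self) -> np.ndarray:
        """Points rounded to the nearest pixel, as an (n, 2) int array."""
        return np.rint(self.points).astype(np.int64)

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        r, c = self.points[:, 0], self.points[:, 1]
        if len(self) and not (
            (r >= 0).all() and (r <= h - 1).all() and (c >= 0).all() and (c <= w - 1).all()
        ):
            raise ValueError(f"centroids fall outside image of shape {shape}")

    @classmethod
    def empty(cls) -> "CentroidSet":
        return cls(np.empty(0, dtype=np.int64), np.empty((0, 2)))

    @classmethod
    def from_points(cls, points) -> "CentroidSet":
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        return cls(np.arange(1, len(pts) + 1), pts)


def validate_ternary(label: np.ndarray) -> np.ndarray:
    """Check a ternary pseudo-label holds only values {0, 1, 2}."""
    arr = np.asarray(label)
    bad = np.setdiff1d(np.unique(arr), sorted(TERNARY_VALUES))
    if bad.size:
        raise ValueError(f"ternary label contains invalid values {bad.tolist()}")
    return arr.astype(np.uint8)


def instance_ids(instance_map: np.ndarray) -> np.ndarray:
    """Positive instance ids present in an instance map, sorted."""
    ids = np.unique(instance_map)
    return ids[ids > 0]


def compact_instances(instance_map: np.ndarray) -> np.ndarray:
    """Relabel an instance map to consecutive ids 1..N (0 stays background)."""
    out = np.zeros_like(instance_map, dtype=np.int32)
    for new_id, old_id in enumerate(instance_ids(instance_map), start=1):
        out[instance_map == old_id] = new_id
    return out


@dataclass
class ModelOutput:
    """Full-image model prediction: foreground probability and k Gaussian maps."""

    seg_prob: np.ndarray
    gauss_maps: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0)))

    @property
    def n_gauss_branches(self) -> int:
        return int(self.gauss_maps.shape[0])
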