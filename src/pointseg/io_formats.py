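"""Readers and writers for images, instance-label masks, point CSVs and
ternary pseudo-labels, plus the dataset directory convention.

All coordinates are 0-based ``(row, col)`` with row pointing down.
Instance masks are 16-bit grayscale PNG/TIFF; ternary labels are 8-bit
palette PNGs restricted to values {0, 1, 2}; points CSVs have the header
``instance_id,row,col``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import CentroidSet, validate_ternary

POINTS_COLUMNS = ["instance_id", "row", "col"]

# palette for ternary PNGs: background black, foreground green, ignored gray
_TERNARY_PALETTE = [0, 0, 0, 0, 200, 0, 128, 128, 128] + [0] * (256 * 3 - 9)


@dataclass(frozen=True)
class DatasetItem:
    """One image with its point annotation and optional ground truth."""

    image_id: str
    image_path: Path
    points_path: Path
    gt_path: Path | None = None

    def load(self):
        image = read_image(self.image_path)
        points = read_points(self.points_path)
        gt = read_instance_map(self.gt_path) if self.gt_path else None
        return image, points, gt


def read_image(path) -> np.ndarray:
    """Read an RGB image tile as (H, W, 3) uint8."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return arr.astype(np.uint8)


def write_image(image: np.ndarray, path) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    Image.fromarray(image.astype(np.uint8), mode="RGB").save(path)


def read_instance_map(path) -> np.ndarray:
    """Read a 16-bit (or 8-bit) single-channel instance-label image."""
    with Image.open(path) as im:
        if im.mode not in ("I", "I;16", "L", "P"):
            raise ValueError(
                f"{path}: expected a single-channel label image, got mode {im.mode!r}"
            )
        # palette images carry raw indices; everything else goes through "I"
        arr = np.asarray(im) if im.mode == "P" else np.asarray(im.convert("I"))
    return arr.astype(np.int32)


def write_instance_map(instances: np.ndarray, path) -> None:
    instances = np.asarray(instances)
    if instances.ndim != 2 or instances.min() < 0:
        raise ValueError("instance map must be a 2-D non-negative integer image")
    if instances.max() > np.iinfo(np.uint16).max:
        raise ValueError("instance ids exceed 16-bit range")
    Image.fromarray(instances.astype(np.uint16)).save(path)


def read_points(path) -> CentroidSet:
    """Read a points CSV with header ``instance_id,row,col``."""
    df = pd.read_csv(path)
    if list(df.columns) != POINTS_COLUMNS:
        raise ValueError(
            f"{path}: malformed points CSV, expected columns {POINTS_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        return CentroidSet.empty()
    return CentroidSet(
        df["instance_id"].to_numpy(np.int64), df[["row", "col"]].to_numpy(np.float64)
    )


def write_points(points: CentroidSet, path) -> None:
    df = pd.DataFrame(
        {
            "instance_id": points.ids,
            "row": points.points[:, 0],
            "col": points.points[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_ternary(path) -> np.ndarray:
    """Read a ternary pseudo-label (values {0,1,2}) from an 8-bit PNG."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("P") if im.mode == "P" else im.convert("L"))
    return validate_ternary(arr)


def write_ternary(label: np.ndarray, path) -> None:
    label = validate_ternary(label)
    im = Image.fromarray(label.astype(np.uint8), mode="P")
    im.putpalette(_TERNARY_PALETTE)
    im.save(path)


def discover_dataset(directory, require_gt: bool = False) -> list[DatasetItem]:
    """Scan a directory laid out as ``<id>.png`` + ``<id>_points.csv``
    (+ optional ``<id>_label.png``) into dataset items."""
    directory = Path(directory)
    items = []
    for points_path in sorted(directory.glob("*_points.csv")):
        image_id = points_path.name[: -len("_points.csv")]
        image_path = directory / f"{image_id}.png"
        if not image_path.exists():
            image_path = directory / f"{image_id}.tiff"
        if not image_path.exists():
            raise FileNotFoundError(f"no image found for annotation {points_path}")
        gt_path = directory / f"{image_id}_label.png"
        if not gt_path.exists():
            if require_gt:
                raise FileNotFoundError(f"no ground truth for {image_id}")
            gt_path = None
        items.append(DatasetItem(image_id, image_path, points_path, gt_path))
    if not items:
        raise FileNotFoundError(f"no '*_points.csv' annotations found in {directory}")
    return items
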