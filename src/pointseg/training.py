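"""Training driver: patch sampling/augmentation, the Adam optimisation
loop, label-update scheduling, checkpointing, and the two-cycle
protocol.

Defaults follow the full-scale recipe (120 epochs, batch 8, Adam with
learning rate and weight decay 1e-4, 16 overlapping 250-px crops per
image augmented down to 224-px patches, EMA label updates from epoch 60
every 10 epochs, two training cycles). Desk-scale runs shrink the
numbers through the same config, never through different code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .core import IGNORED, CentroidSet
from .label_update import LabelUpdater, UpdateSchedule, refine_labels_kmeans
from .losses import LossWeights, total_loss
from .network import ModelConfig, SegmentationModel, build_model
from .pseudolabels import (
    DEFAULT_RADII,
    distance_transform,
    gaussian_stack,
    initial_cluster_label,
    voronoi_label,
)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 120
    batch_size: int = 8
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    patches_per_image: int = 16
    crop_size_stage1: int = 250
    crop_size_final: int = 224
    radii: tuple = DEFAULT_RADII
    update_labels: bool = True
    loss_weights: LossWeights = field(default_factory=LossWeights)
    schedule: UpdateSchedule = field(default_factory=UpdateSchedule)
    seed: int = 0

    def __post_init__(self):
        if self.crop_size_final > self.crop_size_stage1:
            raise ValueError("final crop must not exceed the stage-1 crop")
        if min(self.epochs, self.batch_size, self.patches_per_image) < 1:
            raise ValueError("epochs, batch_size and patches_per_image must be >= 1")


@dataclass
class TrainingImage:
    """One training tile with its (evolving) pseudo-labels."""

    image: np.ndarray
    points: CentroidSet
    vor: np.ndarray
    gauss: np.ndarray           # (k, H, W)
    distance: np.ndarray
    updater: LabelUpdater

    @property
    def cluster(self) -> np.ndarray:
        return self.updater.current_label


def prepare_training_images(
    dataset, config: TrainConfig, lo: float = 0.3, hi: float = 0.7
) -> list[TrainingImage]:
    """Build all pseudo-labels for (image, points) pairs.

    ``dataset`` is an iterable of objects with ``image`` and ``points``
    attributes (synthetic scenes qualify) or (image, points) tuples.
    """
    out = []
    for entry in dataset:
        if isinstance(entry, tuple):
            image, points = entry
        else:
            image, points = entry.image, entry.points
        shape = image.shape[:2]
        dist = distance_transform(points, shape)
        clu = initial_cluster_label(image, points, dist)
        out.append(
            TrainingImage(
                image=image,
                points=points,
                vor=voronoi_label(points, shape),
                gauss=gaussian_stack(points, shape, config.radii).masks,
                distance=dist,
                updater=LabelUpdater(config.schedule, clu, lo=lo, hi=hi),
            )
        )
    return out


# ------------------------------------------------------------------ patches
def _grid_starts(extent: int, crop: int, n: int) -> np.ndarray:
    if extent <= crop:
        return np.zeros(n, dtype=int)
    return np.round(np.linspace(0, extent - crop, n)).astype(int)


def make_patches(
    image: np.ndarray,
    labels: dict[str, np.ndarray],
    config: TrainConfig,
    rng: np.random.Generator,
) -> list[dict[str, np.ndarray]]:
    """Cut ``patches_per_image`` overlapping stage-1 crops and reduce each
    to a randomly flipped/rotated ``crop_size_final`` patch, applying the
    identical geometric transform to the image and every label.

    Images smaller than the crop are padded: reflect for the image and
    Gaussian masks, ignore-class for ternary labels.
    """
    arrays = {"image": np.moveaxis(np.asarray(image, np.float64) / 255.0, -1, 0)}
    for key, lab in labels.items():
        arr = np.asarray(lab)
        arrays[key] = arr[None] if arr.ndim == 2 else arr
    h, w = image.shape[:2]
    crop = config.crop_size_stage1
    final = config.crop_size_final
    if h < crop or w < crop:
        pad_h, pad_w = max(0, crop - h), max(0, crop - w)
        padded = {}
        for key, arr in arrays.items():
            if key in ("vor", "cluster"):
                padded[key] = np.pad(
                    arr, ((0, 0), (0, pad_h), (0, pad_w)), constant_values=IGNORED
                )
            else:
                padded[key] = np.pad(arr, ((0, 0), (0, pad_h), (0, pad_w)))
        arrays, h, w = padded, max(h, crop), max(w, crop)

    n_side = int(np.ceil(np.sqrt(config.patches_per_image)))
    rows = _grid_starts(h, crop, n_side)
    cols = _grid_starts(w, crop, n_side)
    positions = [(r, c) for r in rows for c in cols][: config.patches_per_image]

    patches = []
    for r0, c0 in positions:
        sub = {k: a[:, r0 : r0 + crop, c0 : c0 + crop] for k, a in arrays.items()}
        k_rot = int(rng.integers(4))
        do_flip = bool(rng.integers(2))
        fr = int(rng.integers(0, crop - final + 1))
        fc = int(rng.integers(0, crop - final + 1))
        example = {}
        for key, a in sub.items():
            a = np.rot90(a, k_rot, axes=(1, 2))
            if do_flip:
                a = a[:, :, ::-1]
            example[key] = np.ascontiguousarray(a[:, fr : fr + final, fc : fc + final])
        patches.append(example)
    return patches


# ----------------------------------------------------------------- training
@dataclass
class TrainResult:
    model: SegmentationModel
    loss_history: list[dict]            # one entry per epoch (across cycles)
    label_events: list[tuple[int, int, str]]  # (cycle, epoch, kind)
    run_dir: Path | None = None


def _epoch_pass(model, images, config, rng, optimizer) -> dict[str, float]:
    """One optimisation epoch over freshly augmented patches."""
    examples = []
    for im in images:
        labels = {"vor": im.vor, "cluster": im.cluster}
        if model.n_gauss_branches:
            labels["gauss"] = im.gauss
        examples.extend(make_patches(im.image, labels, config, rng))
    order = rng.permutation(len(examples))
    sums: dict[str, float] = {}
    n_batches = 0
    for b0 in range(0, len(order), config.batch_size):
        batch = [examples[i] for i in order[b0 : b0 + config.batch_size]]
        x = Tensor(np.stack([ex["image"] for ex in batch]))
        vor = np.stack([ex["vor"][0] for ex in batch])
        clu = np.stack([ex["cluster"][0] for ex in batch])
        seg_probs, gauss = model.forward(x)
        gmasks = (
            np.stack([ex["gauss"] for ex in batch]) if "gauss" in batch[0] else None
        )
        loss, comps = total_loss(
            seg_probs, vor, clu, gauss, gmasks, weights=config.loss_weights
        )
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"training diverged: loss={loss.item()}")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        for key, val in comps.items():
            sums[key] = sums.get(key, 0.0) + val
        n_batches += 1
    return {k: v / n_batches for k, v in sums.items()}


def train(
    dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    run_dir=None,
    resume_from=None,
) -> TrainResult:
    """Run the full multi-cycle protocol and return the trained model.

    Cycle 1 trains on the initial pseudo-labels under the EMA update
    schedule; afterwards each image's cluster label is regenerated by
    the 5-feature k-means and cycle 2 repeats the schedule on those.
    Fully deterministic given the two config seeds.
    """
    cfg = train_config
    model = build_model(model_config)
    images = prepare_training_images(dataset, cfg)
    optimizer = Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    run_dir = Path(run_dir) if run_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)

    start_cycle, start_epoch = 1, 1
    if resume_from is not None:
        start_cycle, start_epoch = _load_checkpoint(resume_from, model, optimizer)

    history: list[dict] = []
    events: list[tuple[int, int, str]] = []
    due = {e: kind for kind, e in cfg.schedule.events(cfg.epochs)}
    for cycle in range(start_cycle, cfg.schedule.cycles + 1):
        first_epoch = start_epoch if cycle == start_cycle else 1
        for epoch in range(first_epoch, cfg.epochs + 1):
            rng = np.random.default_rng(
                (cfg.seed * 1_000_003 + cycle * 10_007 + epoch) % (2**31)
            )
            comps = _epoch_pass(model, images, cfg, rng, optimizer)
            comps.update({"cycle": cycle, "epoch": epoch})
            history.append(comps)
            if cfg.update_labels:
                for im in images:
                    im.updater.on_epoch_end(
                        epoch, lambda im=im: model.predict(im.image).seg_prob
                    )
                if epoch in due:
                    events.append((cycle, epoch, due[epoch]))
            if run_dir is not None:
                _save_checkpoint(run_dir, model, optimizer, cycle, epoch, history)
        if cycle < cfg.schedule.cycles and cfg.update_labels:
            # seed the next cycle: k-means over colour+distance+probability
            for im in images:
                prob = model.predict(im.image).seg_prob
                refined = refine_labels_kmeans(im.image, prob, im.distance)
                im.updater.start_new_cycle(refined)
            events.append((cycle, cfg.epochs, "kmeans-refine"))

    if run_dir is not None:
        model.save(run_dir / "model_final.npz")
        (run_dir / "history.json").write_text(json.dumps(history, indent=1))
    return TrainResult(model=model, loss_history=history, label_events=events, run_dir=run_dir)


def _save_checkpoint(run_dir: Path, model, optimizer, cycle, epoch, history):
    state = dict(model.state_dict())
    np.savez_compressed(
        run_dir / "checkpoint.npz",
        __cycle=np.array(cycle),
        __epoch=np.array(epoch),
        **{f"p{k}": v for k, v in state.items()},
    )
    (run_dir / "history.json").write_text(json.dumps(history, indent=1))


def _load_checkpoint(path, model, optimizer):
    with np.load(path) as data:
        cycle = int(data["__cycle"])
        epoch = int(data["__epoch"])
        state = {k[1:]: data[k] for k in data.files if k.startswith("p")}
    model.load_state_dict(state)
    return cycle, epoch + 1
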