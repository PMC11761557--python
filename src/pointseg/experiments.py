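"""Desk-scale experiments runnable on one CPU in minutes.

These drive the full method end to end on synthetic scenes: a compact
backbone, small tiles, shortened cycles. They exist to check the
*directions* the method claims — center-point guidance plus refinement
separates touching nuclei better than plain connected components, and
label updating shrinks the ignored band while improving foreground
accuracy — not to reproduce full-scale benchmark magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .inference import InferenceConfig, run_inference
from .label_update import (
    UpdateSchedule,
    foreground_iou,
    ignored_fraction,
    refine_labels_kmeans,
)
from .metrics import evaluate_pair
from .network import ModelConfig
from .pseudolabels import distance_transform, initial_cluster_label
from .synthetic import SceneConfig, generate_scene
from .training import TrainConfig, train

# Desk-scale study conditions: 64-px tiles of densely packed nuclei
# (~22% foreground, like H&E tiles) with one deliberately touching pair
# per scene and jittered points.
DESK_SCENE = SceneConfig(
    height=64,
    width=64,
    n_nuclei=14,
    radius_range=(3, 6),
    elongation_prob=0.25,
    touching_pairs=1,
    point_jitter_sd=1.0,
)
# Gaussian radii scaled to the desk-scale nucleus sizes (sigma = r/3 as
# always): kernels must stay below the typical center spacing or adjacent
# kernels overlap and center prediction degrades
DESK_RADII = (3, 5, 7, 9)

DESK_MODEL = ModelConfig(n_gauss_branches=4, backbone="tiny", patch_grid=4, seed=0)
# learning rate raised to 1e-3: the full-scale 1e-4 is matched to a ResNet34
# at batch-8/224px and undertrains the desk-scale backbone badly
DESK_TRAIN = TrainConfig(
    epochs=18,
    batch_size=8,
    learning_rate=1e-3,
    patches_per_image=4,
    crop_size_stage1=64,
    crop_size_final=56,
    radii=DESK_RADII,
    schedule=UpdateSchedule(warmup_epochs=8, update_interval=4, alpha=0.1, cycles=2),
)
DESK_INFER = InferenceConfig(patch_size=64, overlap=16, min_center_area=5)


def make_scenes(n: int, seed: int, config: SceneConfig = DESK_SCENE) -> list:
    return [generate_scene(replace(config, seed=seed + i)) for i in range(n)]


@dataclass
class AblationResult:
    full_metrics: dict
    seg_only_metrics: dict
    full_history: list
    seg_only_history: list
    n_train: int
    n_test: int

    def summary(self) -> dict:
        return {
            "full_aji": self.full_metrics["aji"],
            "seg_only_aji": self.seg_only_metrics["aji"],
            "full_pq": self.full_metrics["pq"],
            "seg_only_pq": self.seg_only_metrics["pq"],
            "full_first_epoch_loss": self.full_history[0]["total"],
            "full_last_epoch_loss": self.full_history[-1]["total"],
        }


def run_ablation_experiment(
    seed: int = 0,
    n_train: int = 16,
    n_test: int = 6,
    model_config: ModelConfig = DESK_MODEL,
    train_config: TrainConfig = DESK_TRAIN,
    infer_config: InferenceConfig = DESK_INFER,
) -> AblationResult:
    """Train the full model and the segmentation-only ablation on the same
    synthetic scenes and evaluate both on held-out scenes.

    The full variant has k Gaussian branches, point-guided attention,
    label updating, and Voronoi instance refinement at test time; the
    ablation is a single segmentation decoder whose instance map is the
    thresholded connected components.
    """
    train_scenes = make_scenes(n_train, seed=seed * 10_000 + 1)
    test_scenes = make_scenes(n_test, seed=seed * 10_000 + 5_001)

    full_cfg = replace(model_config, seed=seed)
    full = train(train_scenes, full_cfg, replace(train_config, seed=seed))

    ablate_model = replace(
        model_config, n_gauss_branches=0, use_attention=False, seed=seed
    )
    ablate_train = replace(
        train_config,
        seed=seed,
        update_labels=False,
        schedule=replace(train_config.schedule, cycles=1),
        # same number of optimisation epochs overall as the full model
        epochs=train_config.epochs * train_config.schedule.cycles,
    )
    seg_only = train(train_scenes, ablate_model, ablate_train)

    def eval_model(model):
        reports = []
        for scene in test_scenes:
            pred, _ = run_inference(model, scene.image, infer_config)
            reports.append(evaluate_pair(scene.gt_instances, pred).as_dict())
        return {k: float(np.mean([r[k] for r in reports])) for k in reports[0]}

    return AblationResult(
        full_metrics=eval_model(full.model),
        seg_only_metrics=eval_model(seg_only.model),
        full_history=full.loss_history,
        seg_only_history=seg_only.loss_history,
        n_train=n_train,
        n_test=n_test,
    )


def simulate_label_update(
    n_scenes: int = 10, seed: int = 0, scene_config: SceneConfig = DESK_SCENE
) -> dict:
    """One simulated update cycle on synthetic scenes.

    Stands in for a trained model with a plausible probability map — the
    smoothed, lightly corrupted ground-truth foreground — then compares
    the k-means-refined cluster labels with the initial ones: ignored
    fraction should drop and foreground IoU against GT should rise.
    """
    rows = []
    for i in range(n_scenes):
        scene = generate_scene(replace(scene_config, seed=seed * 10_000 + 777 + i))
        rng = np.random.default_rng(seed * 10_000 + 777 + i)
        gt_fg = scene.gt_instances > 0
        dist = distance_transform(scene.points, gt_fg.shape)
        initial = initial_cluster_label(scene.image, scene.points, dist)
        prob = ndi.gaussian_filter(gt_fg.astype(float), 0.75)
        prob = np.clip(prob + rng.normal(0, 0.05, prob.shape), 0, 1)
        refined = refine_labels_kmeans(scene.image, prob, dist)
        rows.append(
            {
                "initial_ignored": ignored_fraction(initial),
                "refined_ignored": ignored_fraction(refined),
                "initial_iou": foreground_iou(initial, gt_fg),
                "refined_iou": foreground_iou(refined, gt_fg),
            }
        )
    return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}


class OracleModel:
    """A stand-in 'perfect' model emitting the ground-truth semantic mask
    and Gaussian center maps built from the true points; isolates the
    inference strategy from network quality."""

    def __init__(self, scene, radii=DESK_RADII):
        from .pseudolabels import gaussian_stack

        self.n_gauss_branches = len(radii)
        shape = scene.gt_instances.shape
        self._seg = (scene.gt_instances > 0).astype(float)
        self._gauss = gaussian_stack(scene.points, shape, radii).masks
        self._shape = shape

    def predict(self, image):
        from .core import ModelOutput

        if image.shape[:2] != self._shape:
            raise ValueError("oracle model is bound to one scene")
        return ModelOutput(seg_prob=self._seg, gauss_maps=self._gauss)


def oracle_recovery(
    n_scenes: int = 6, seed: int = 0, scene_config: SceneConfig = DESK_SCENE
) -> dict:
    """Feed GT semantic masks + GT center points through the inference
    pipeline and count instances: coarse connected components merge the
    touching pairs, the refined output should match the GT count."""
    coarse_counts, refined_counts, gt_counts = [], [], []
    for i in range(n_scenes):
        scene = generate_scene(replace(scene_config, seed=seed * 10_000 + 31 + i))
        model = OracleModel(scene)
        cfg = replace(DESK_INFER, max_refine_iters=10)
        from .inference import label_segmentation, tile_predict

        out = tile_predict(model, scene.image, cfg)
        coarse_cc = label_segmentation(out.seg_prob, cfg.fg_threshold)
        refined, _ = run_inference(model, scene.image, cfg)
        gt_counts.append(int(scene.gt_instances.max()))
        coarse_counts.append(int(coarse_cc.max()))
        refined_counts.append(int(refined.max()))
    return {
        "gt_instances": int(np.sum(gt_counts)),
        "coarse_cc_instances": int(np.sum(coarse_counts)),
        "refined_instances": int(np.sum(refined_counts)),
    }
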