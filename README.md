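# pointseg

Nuclei instance segmentation in histopathology images from **point
annotations only** — one `(row, col)` click per nucleus instead of full
pixel-level masks.

Dense nuclear masks are expensive to annotate; a single center point per
nucleus is roughly an order of magnitude cheaper. `pointseg` turns those
points into full instance segmentations with three cooperating ideas:

1. **Pseudo-labels from points.** The Voronoi partition of the annotated
   points gives a ternary *Voronoi label* (ridges → background, dilated
   points → foreground, rest ignored) that encodes the separation between
   neighbouring nuclei; 3-way k-means over per-pixel colour + clipped
   distance-to-point features gives a *cluster label*; and each point is
   expanded into multi-scale *Gaussian masks*
   `M_i(x, y) = exp(−d_i²/(2σ_i²))` for `d_i < r_i` (else 0), with radii
   `r = 7, 9, 11, 13` and `σ_i = r_i/3`, used as dense center-point
   regression targets.
2. **A shared encoder with k+1 decoders and point-guided attention.** A
   residual encoder feeds one segmentation decoder (2-class softmax) and
   k Gaussian decoders (sigmoid). At every decoder level the feature maps
   are split into 7×7 patches and attended: Query/Key come from the mean
   of the k Gaussian-branch features, Value from the segmentation
   feature — `Attn(Q, K, V) = softmax(QKᵀ/√d_k)V` — steering the
   segmentation decoder toward the trustworthy evidence near the true
   points. Training minimises
   `L = λ₁·L_vor + (2−λ₁)·L_clu + λ₂·L_gauss` with Dice + cross-entropy
   for the two segmentation terms (ignored pixels excluded) and a
   weighted MSE (weight 10 where the mask is positive) for the Gaussian
   branches; `λ₁ = λ₂ = 1`.
3. **Pseudo-label updating and Voronoi instance refinement.** After a
   warm-up the model's own probability map fills the ignored pixels of
   the cluster label (`W₀ = K` where decided, `p` where ignored) and is
   then tracked by an exponential moving average
   `W_n = α·p_n + (1−α)·W_{n−1}` (α = 0.1, every 10 epochs),
   re-thresholded into training labels; after a full cycle, 5-feature
   k-means (RGB, clipped distance, probability) regenerates the cluster
   labels for a second training cycle. At test time the k Gaussian maps
   vote (majority ≥ ⌈k/2⌉) for center-foreground, surviving component
   centroids seed a Voronoi partition that splits the thresholded
   segmentation into instances, and a refinement loop adds missing
   centroids, drops background centroids and merges sub-regions below
   10% of their instance until every instance holds exactly one
   centroid. The refinement re-partitions the foreground but never
   changes it.

Evaluation ships with the field's five instance metrics: object-level
Dice, AJI (aggregated Jaccard index), and DQ/SQ/PQ (panoptic quality
family, matches at IoU > 0.5, PQ = DQ·SQ).

Everything is testable offline: `pointseg.synthetic` renders H&E-like
tiles (purple-ish elliptical nuclei on a textured pink-ish background,
including deliberately touching pairs) with exact instance masks and
jittered point annotations. The neural network and its training loop run
on a small reverse-mode autograd engine included in the package
(`pointseg.autograd`), so the whole pipeline needs nothing beyond the
scientific Python stack.

## Worked example

```python
import numpy as np
from dataclasses import replace
from pointseg.experiments import DESK_MODEL, DESK_TRAIN, DESK_INFER, make_scenes
from pointseg.training import train
from pointseg.inference import run_inference
from pointseg.metrics import evaluate_pair

scenes = make_scenes(16, seed=10001)          # 64x64 tiles, 14 nuclei each
result = train(scenes, replace(DESK_MODEL, seed=1), replace(DESK_TRAIN, seed=1))

test = make_scenes(6, seed=15001)
pred, centers = run_inference(result.model, test[0].image, DESK_INFER)
report = evaluate_pair(test[0].gt_instances, pred)
print(f"instances: {pred.max()} (gt {test[0].gt_instances.max()})")
print({k: round(v, 3) for k, v in report.as_dict().items()})
```

Output from this exact run:

```
instances: 14 (gt 14)
{'dice_obj': 0.849, 'aji': 0.705, 'dq': 0.857, 'sq': 0.811, 'pq': 0.695}
```

All 14 nuclei are recovered — including the deliberately touching pair
that a plain connected-component labelling merges — with AJI ≈ 0.7 on
a 64×64 tile after a few minutes of CPU training. The Gaussian-branch
centroids plus Voronoi refinement are what separate the touching pair;
an ablated segmentation-only model scores a lower AJI on the same
held-out scenes because merged pairs count heavily against it.

There is also a CLI: `pointseg simulate | make-labels | train |
update-labels | infer | eval` (see `pointseg --help`).

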