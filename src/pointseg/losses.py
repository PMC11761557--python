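"""Training objectives.

The segmentation branch is supervised twice — once by the Voronoi label
and once by the cluster label — each with Dice + cross-entropy computed
only over non-ignored pixels. The Gaussian branches use a weighted MSE
with weight 10 on pixels where the target mask is positive and 1
elsewhere, averaged over branches. The total objective is

    L_total = lambda1 * L_vor + (2 - lambda1) * L_clu + lambda2 * L_gauss

with both weights defaulting to 1.

Every function accepts either plain numpy arrays or autograd Tensors
and returns a scalar :class:`~pointseg.autograd.Tensor` so the same
code path serves evaluation and backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor
from .core import FOREGROUND, IGNORED

_LOG_CLAMP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 1.0
    lambda2: float = 1.0
    fg_weight: float = 10.0
    bg_weight: float = 1.0
    eps: float = 1e-5

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.fg_weight, self.bg_weight, self.eps) < 0:
            raise ValueError("loss weights must be non-negative")


def weighted_mse(
    gauss_preds,
    gauss_masks,
    ignore_mask: np.ndarray | None = None,
    fg_weight: float = 10.0,
    bg_weight: float = 1.0,
) -> Tensor:
    """Per-branch weighted MSE against the Gaussian targets, averaged over
    the k branches. ``gauss_preds`` is (k, H, W) (a leading batch axis is
    allowed); targets may be a GaussianMaskStack or a matching array."""
    masks = np.asarray(getattr(gauss_masks, "masks", gauss_masks), dtype=np.float64)
    preds = as_tensor(gauss_preds)
    if preds.shape != masks.shape:
        raise ValueError(f"shape mismatch: preds {preds.shape} vs masks {masks.shape}")
    keep = np.ones(masks.shape, dtype=np.float64)
    if ignore_mask is not None:
        keep = keep * np.broadcast_to(~np.asarray(ignore_mask, bool), masks.shape)
    n_kept_per_branch = keep.reshape(masks.shape[0], -1).sum(axis=1) if masks.ndim == 3 \
        else keep.reshape(masks.shape[0], masks.shape[1], -1).sum(axis=-1)
    if np.any(n_kept_per_branch == 0):
        raise ValueError("weighted MSE: no non-ignored pixels in some branch")
    w = np.where(masks > 0, fg_weight, bg_weight) * keep
    sq = ag.power(preds - Tensor(masks), 2.0)
    # mean over non-ignored pixels per branch, then mean over branches
    spatial_axes = tuple(range(masks.ndim - 2, masks.ndim))
    per_branch = ag.tsum(sq * Tensor(w), axis=spatial_axes)
    per_branch = per_branch * Tensor(1.0 / n_kept_per_branch)
    return ag.tmean(per_branch)


def dice_loss(pred_prob, target_binary, ignore_mask=None, eps: float = 1e-5) -> Tensor:
    """Foreground Dice loss, sums restricted to non-ignored pixels.

    ``1 - (2 sum(p t) + eps) / (sum(p^2) + sum(t^2) + eps)`` with sums
    over the last two (spatial) axes; any leading batch axis is averaged
    over. The eps regulariser makes the all-ignored case evaluate to 0.
    """
    p = as_tensor(pred_prob)
    t = np.asarray(target_binary, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    keep = np.ones_like(t)
    if ignore_mask is not None:
        keep = keep * (~np.asarray(ignore_mask, bool))
    t = t * keep
    p = p * Tensor(keep)
    axes = (-2, -1)
    num = ag.tsum(p * Tensor(t), axis=axes) * 2.0 + eps
    den = ag.tsum(ag.power(p, 2.0), axis=axes) + Tensor((t ** 2).sum(axis=axes)) + eps
    return ag.tmean(1.0 - num / den)


def ce_loss(pred_class_probs, target_ternary) -> Tensor:
    """Mean negative log-probability of the true class over pixels whose
    ternary label is not ignored. ``pred_class_probs`` is (C, H, W) —
    probabilities normalised over the class axis — or batched
    (B, C, H, W) with a (B, H, W) target; per-sample means are averaged
    over the batch."""
    p = as_tensor(pred_class_probs)
    target = np.asarray(target_ternary)
    batched = p.ndim == 4
    if (batched and (p.shape[0],) + p.shape[2:] != target.shape) or (
        not batched and (p.ndim != 3 or p.shape[1:] != target.shape)
    ):
        raise ValueError(
            f"probs of shape {p.shape} do not match target {target.shape}"
        )
    n_classes = p.shape[1] if batched else p.shape[0]
    class_axis = 1 if batched else 0
    keep = target != IGNORED
    n_kept = keep.sum(axis=(-2, -1))
    if np.any(n_kept == 0):
        raise ValueError("cross-entropy: every pixel is ignored")
    onehot = np.stack(
        [(target == c) & keep for c in range(n_classes)], axis=class_axis
    ).astype(np.float64)
    logp = ag.log(ag.clip(p, _LOG_CLAMP, 1.0)) * Tensor(onehot)
    if batched:
        picked = ag.tsum(logp, axis=(1, 2, 3))
        return ag.tmean(picked * Tensor(-1.0 / n_kept))
    return ag.tsum(logp) * (-1.0 / float(n_kept))


def seg_loss(seg_probs, ternary_label, eps: float = 1e-5) -> Tensor:
    """Dice + CE of the 2-class segmentation output against one ternary
    label; ``seg_probs`` is (2, H, W) or batched (B, 2, H, W)."""
    label = np.asarray(ternary_label)
    ignore = label == IGNORED
    fg_prob = as_tensor(seg_probs)
    fg_axis = 1 if fg_prob.ndim == 4 else 0
    dice = dice_loss(
        ag.take(fg_prob, FOREGROUND, fg_axis),
        (label == FOREGROUND).astype(float),
        ignore,
        eps=eps,
    )
    return dice + ce_loss(fg_prob, label)


def total_loss(
    seg_probs,
    vor_label,
    clu_label,
    gauss_preds=None,
    gauss_masks=None,
    weights: LossWeights = LossWeights(),
) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the Voronoi, cluster and Gaussian objectives.

    Returns the differentiable total plus a dict of float components
    for logging.
    """
    w = weights
    l_vor = seg_loss(seg_probs, vor_label, eps=w.eps)
    l_clu = seg_loss(seg_probs, clu_label, eps=w.eps)
    total = l_vor * w.lambda1 + l_clu * (2.0 - w.lambda1)
    components = {"vor": l_vor.item(), "clu": l_clu.item(), "gauss": 0.0}
    if gauss_preds is not None and w.lambda2 > 0:
        l_gauss = weighted_mse(
            gauss_preds, gauss_masks, fg_weight=w.fg_weight, bg_weight=w.bg_weight
        )
        total = total + l_gauss * w.lambda2
        components["gauss"] = l_gauss.item()
    components["total"] = total.item()
    return total, components
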