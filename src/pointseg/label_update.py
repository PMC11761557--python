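"""EMA-based pseudo-label updating and post-cycle k-means refinement.

During training the cluster labels are the only labels that evolve
(Voronoi labels are frozen for the whole run). The life cycle within
one training cycle is:

* epochs below the warmup (default 60): labels untouched;
* at the warmup epoch: the model's full-image probability map fills the
  ignored pixels of the cluster label, creating the weight map ``W0``;
* every ``update_interval`` epochs after that: ``W_n = alpha p_n +
  (1 - alpha) W_{n-1}`` followed by re-thresholding into a ternary
  label, with pixels the original cluster label ignored staying ignored;
* after the cycle: a 5-feature k-means (normalised RGB, clipped
  distance-to-point, predicted probability) produces the cluster labels
  that seed the next cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .core import BACKGROUND, FOREGROUND, IGNORED, validate_ternary
from .pseudolabels import DISTANCE_CLIP


@dataclass(frozen=True)
class UpdateSchedule:
    warmup_epochs: int = 60
    update_interval: int = 10
    alpha: float = 0.1
    cycles: int = 2

    def __post_init__(self):
        if min(self.warmup_epochs, self.update_interval, self.cycles) <= 0:
            raise ValueError("schedule fields must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def events(self, n_epochs: int):
        """Planned update events for one cycle of ``n_epochs`` (1-based
        epoch numbers): [('init', e0), ('ema', e1), ...]."""
        out = []
        if n_epochs >= self.warmup_epochs:
            out.append(("init", self.warmup_epochs))
            e = self.warmup_epochs + self.update_interval
            while e <= n_epochs:
                out.append(("ema", e))
                e += self.update_interval
        return out


@dataclass
class WeightMap:
    """EMA accumulator of historical foreground predictions, in [0, 1]."""

    W: np.ndarray
    epoch_of_last_update: int = 0

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.float64)
        if W.min() < 0 or W.max() > 1:
            raise ValueError("weight map values must lie in [0, 1]")
        self.W = W


def init_weight_map(cluster_label: np.ndarray, prob: np.ndarray, epoch: int = 0) -> WeightMap:
    """W0 = K where the cluster label is decided (0/1) and the predicted
    probability where it is ignored."""
    K = validate_ternary(cluster_label)
    prob = np.asarray(prob, dtype=np.float64)
    if K.shape != prob.shape:
        raise ValueError("cluster label and probability map shapes disagree")
    W0 = np.where(K == IGNORED, prob, K.astype(np.float64))
    return WeightMap(W=W0, epoch_of_last_update=epoch)


def ema_update(w_prev: WeightMap, prob: np.ndarray, alpha: float, epoch: int | None = None) -> WeightMap:
    """Exponential moving average: ``W_n = alpha p_n + (1-alpha) W_{n-1}``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    prob = np.asarray(prob, dtype=np.float64)
    if prob.shape != w_prev.W.shape:
        raise ValueError("probability map and weight map shapes disagree")
    W = alpha * prob + (1.0 - alpha) * w_prev.W
    return WeightMap(
        W=W,
        epoch_of_last_update=(
            epoch if epoch is not None else w_prev.epoch_of_last_update + 1
        ),
    )


def weight_map_to_label(
    w: WeightMap, original_K: np.ndarray, lo: float = 0.3, hi: float = 0.7
) -> np.ndarray:
    """Threshold a weight map back into a ternary label.

    Pixels the original cluster label ignored stay ignored; elsewhere
    values >= hi become foreground, <= lo background, and the band in
    between is marked uncertain (ignored).
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"need 0 <= lo < hi <= 1, got ({lo}, {hi})")
    K = validate_ternary(original_K)
    label = np.full(K.shape, IGNORED, dtype=np.uint8)
    label[w.W >= hi] = FOREGROUND
    label[w.W <= lo] = BACKGROUND
    label[K == IGNORED] = IGNORED
    return label


def refine_labels_kmeans(
    image: np.ndarray,
    prob: np.ndarray,
    distance_map: np.ndarray,
    n_clusters: int = 3,
    random_state: int = 0,
) -> np.ndarray:
    """Post-cycle refinement: cluster the 5-vector (r, g, b, d, p) per
    pixel and map clusters to {fg, bg, ignored} by mean predicted
    probability (highest -> foreground, lowest -> background, middle ->
    ignored). Seeds the next training cycle's cluster labels."""
    image = np.asarray(image, dtype=np.float64)
    shape = image.shape[:2]
    prob = np.asarray(prob, dtype=np.float64)
    if prob.shape != shape or np.asarray(distance_map).shape != shape:
        raise ValueError("image, probability and distance maps must share shape")
    features = np.column_stack(
        [
            image.reshape(-1, 3) / 255.0,
            np.clip(distance_map, 0, DISTANCE_CLIP).reshape(-1) / DISTANCE_CLIP,
            prob.reshape(-1),
        ]
    )
    if features.std(axis=0).max() < 1e-9:
        warnings.warn("constant features: refined label degenerate, all pixels ignored")
        return np.full(shape, IGNORED, dtype=np.uint8)
    with warnings.catch_warnings():
        # k-means hitting max_iter is a best-effort result, not an error
        warnings.simplefilter("always", ConvergenceWarning)
        km = KMeans(n_clusters=n_clusters, n_init=4, random_state=random_state)
        assignments = km.fit_predict(features).reshape(shape)
    mean_prob = np.array(
        [
            prob[assignments == c].mean() if (assignments == c).any() else -np.inf
            for c in range(n_clusters)
        ]
    )
    order = np.argsort(mean_prob)
    label = np.full(shape, IGNORED, dtype=np.uint8)
    label[assignments == order[-1]] = FOREGROUND
    label[assignments == order[0]] = BACKGROUND
    return label


@dataclass
class LabelUpdater:
    """Per-image label-update state machine driven by the training loop.

    ``on_epoch_end`` receives the 1-based epoch within the current cycle
    and a callable producing the current full-image foreground
    probability map (evaluated lazily, only when an update is due).
    """

    schedule: UpdateSchedule
    initial_cluster_label: np.ndarray
    lo: float = 0.3
    hi: float = 0.7
    weight_map: WeightMap | None = None
    current_label: np.ndarray = field(init=False)
    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.current_label = validate_ternary(self.initial_cluster_label).copy()

    def on_epoch_end(self, epoch: int, prob_fn) -> bool:
        """Apply any due update; returns True if the label changed."""
        s = self.schedule
        if epoch < s.warmup_epochs:
            return False
        if epoch == s.warmup_epochs:
            self.weight_map = init_weight_map(
                self.initial_cluster_label, prob_fn(), epoch
            )
            self.events.append(("init", epoch))
            return False  # the label itself changes only at EMA steps
        since = epoch - s.warmup_epochs
        if self.weight_map is not None and since % s.update_interval == 0:
            self.weight_map = ema_update(self.weight_map, prob_fn(), s.alpha, epoch)
            self.current_label = weight_map_to_label(
                self.weight_map, self.initial_cluster_label, self.lo, self.hi
            )
            self.events.append(("ema", epoch))
            return True
        return False

    def start_new_cycle(self, refined_cluster_label: np.ndarray) -> None:
        """Reset for the next training cycle with refined cluster labels."""
        self.initial_cluster_label = validate_ternary(refined_cluster_label).copy()
        self.current_label = self.initial_cluster_label.copy()
        self.weight_map = None


def ignored_fraction(label: np.ndarray) -> float:
    label = np.asarray(label)
    return float((label == IGNORED).mean())


def foreground_iou(label: np.ndarray, gt_foreground: np.ndarray) -> float:
    """IoU of a ternary label's foreground class against a boolean GT mask."""
    fg = np.asarray(label) == FOREGROUND
    gt = np.asarray(gt_foreground).astype(bool)
    union = (fg | gt).sum()
    return float((fg & gt).sum() / union) if union else 1.0
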