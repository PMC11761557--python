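"""Instance-segmentation metrics: object-level Dice, AJI, and DQ/SQ/PQ.

All metrics compare two integer instance maps (0 = background) of the
same shape, are invariant to instance-id permutations, and live in
[0, 1]. Degenerate conventions: two empty maps score 1 everywhere;
empty-vs-nonempty scores 0 (for PQ the usual TP/FP/FN accounting gives
the same).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _instances(m: np.ndarray) -> dict[int, np.ndarray]:
    m = np.asarray(m)
    return {int(i): m == i for i in np.unique(m) if i > 0}


def _pairwise_overlaps(gt: np.ndarray, pred: np.ndarray):
    """Sparse contingency of instance overlaps: {(gi, pj): n_pixels}."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    both = (gt > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True
    )
    return {(int(g), int(p)): int(n) for (g, p), n in zip(pairs.T, counts)}


def _areas(m: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(np.asarray(m), return_counts=True)
    return {int(i): int(n) for i, n in zip(ids, counts) if i > 0}


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard Index.

    Each ground-truth instance is matched to the prediction instance
    maximising IoU; matched intersections and unions accumulate, every
    unmatched prediction's area is added to the union.
    """
    gt, pred = np.asarray(gt), np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("instance maps must share shape")
    gt_areas, pred_areas = _areas(gt), _areas(pred)
    if not gt_areas and not pred_areas:
        return 1.0
    if not gt_areas or not pred_areas:
        return 0.0
    overlaps = _pairwise_overlaps(gt, pred)
    used = set()
    inter_sum = 0
    union_sum = 0
    for g, g_area in gt_areas.items():
        best_iou, best_p, best_inter = 0.0, None, 0
        for (gg, p), inter in overlaps.items():
            if gg != g:
                continue
            iou = inter / (g_area + pred_areas[p] - inter)
            if iou > best_iou:
                best_iou, best_p, best_inter = iou, p, inter
        if best_p is None:
            union_sum += g_area
        else:
            inter_sum += best_inter
            union_sum += g_area + pred_areas[best_p] - best_inter
            used.add(best_p)
    for p, p_area in pred_areas.items():
        if p not in used:
            union_sum += p_area
    return inter_sum / union_sum if union_sum else 1.0


def panoptic(
    gt: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.5
) -> tuple[float, float, float]:
    """Detection/segmentation/panoptic quality.

    Pairs with IoU strictly above the threshold are matches (unique for
    thresholds >= 0.5); DQ = TP / (TP + FP/2 + FN/2), SQ = mean matched
    IoU, PQ = DQ * SQ. No instances on either side scores (1, 1, 1).
    """
    gt, pred = np.asarray(gt), np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("instance maps must share shape")
    gt_areas, pred_areas = _areas(gt), _areas(pred)
    if not gt_areas and not pred_areas:
        return 1.0, 1.0, 1.0
    overlaps = _pairwise_overlaps(gt, pred)
    matches = []
    for (g, p), inter in overlaps.items():
        iou = inter / (gt_areas[g] + pred_areas[p] - inter)
        if iou > iou_threshold:
            matches.append(iou)
    tp = len(matches)
    fp = len(pred_areas) - tp
    fn = len(gt_areas) - tp
    dq = tp / (tp + 0.5 * fp + 0.5 * fn) if (tp + fp + fn) else 1.0
    sq = float(np.mean(matches)) if matches else 0.0
    return dq, sq, dq * sq


def dice_obj(gt: np.ndarray, pred: np.ndarray) -> float:
    """Object-level Dice: the area-weighted mean of per-object Dice
    scores, averaged symmetrically over the GT->pred matching (each GT
    object against the prediction overlapping it most) and the
    pred->GT matching."""
    gt, pred = np.asarray(gt), np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("instance maps must share shape")
    gt_areas, pred_areas = _areas(gt), _areas(pred)
    if not gt_areas and not pred_areas:
        return 1.0
    if not gt_areas or not pred_areas:
        return 0.0
    overlaps = _pairwise_overlaps(gt, pred)

    def side(a_areas, b_areas, pair_key):
        total = sum(a_areas.values())
        acc = 0.0
        for a, a_area in a_areas.items():
            best_inter, best_b = 0, None
            for key, inter in overlaps.items():
                if pair_key(key)[0] != a:
                    continue
                if inter > best_inter:
                    best_inter, best_b = inter, pair_key(key)[1]
            if best_b is not None:
                dice = 2.0 * best_inter / (a_area + b_areas[best_b])
                acc += a_area / total * dice
        return acc

    gt_side = side(gt_areas, pred_areas, lambda k: (k[0], k[1]))
    pred_side = side(pred_areas, gt_areas, lambda k: (k[1], k[0]))
    return 0.5 * (gt_side + pred_side)


def pixel_iou(gt: np.ndarray, pred: np.ndarray) -> float:
    """Object-free foreground IoU (upper bounds AJI)."""
    g, p = np.asarray(gt) > 0, np.asarray(pred) > 0
    union = (g | p).sum()
    return float((g & p).sum() / union) if union else 1.0


@dataclass(frozen=True)
class MetricsReport:
    dice_obj: float
    aji: float
    dq: float
    sq: float
    pq: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dice_obj": self.dice_obj,
            "aji": self.aji,
            "dq": self.dq,
            "sq": self.sq,
            "pq": self.pq,
        }


def evaluate_pair(gt: np.ndarray, pred: np.ndarray) -> MetricsReport:
    dq, sq, pq = panoptic(gt, pred)
    return MetricsReport(
        dice_obj=dice_obj(gt, pred), aji=aji(gt, pred), dq=dq, sq=sq, pq=pq
    )


def evaluate_dataset(pairs: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Per-image metrics plus a dataset-mean row, as a DataFrame indexed
    by image id."""
    rows = {
        image_id: evaluate_pair(gt, pred).as_dict()
        for image_id, (gt, pred) in pairs.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["mean"] = df.mean()
    return df
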