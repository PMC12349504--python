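"""Multi-label classification and pair-level evaluation metrics.

Precision/recall/F1 are computed from thresholded predictions (macro over
categories by default, micro also reported); per-class average precision is
taken over the full score ranking with the precision-at-each-positive
convention (no 11-point or trapezoid interpolation), and mAP is the
unweighted mean over classes that have at least one positive. All values are
reported as percentages in [0, 100].

An optional attention-localization mAP derives one box per label from the
co-attention heatmap (threshold at half its maximum, largest connected
component) and scores it against ground-truth boxes at IoU 0.5 / 0.75.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import average_precision_score, precision_recall_fscore_support

__all__ = [
    "DecisionRule",
    "MetricsBundle",
    "harmonic_f1",
    "classification_metrics",
    "pair_metrics",
    "attention_localization_map",
    "box_iou",
]

logger = logging.getLogger(__name__)


@dataclass
class DecisionRule:
    """Per-class probability threshold; a pair is predicted present iff both
    member probabilities clear their thresholds."""

    threshold: float | np.ndarray = 0.5

    def thresholds(self, n_classes: int) -> np.ndarray:
        t = np.broadcast_to(np.asarray(self.threshold, dtype=float), (n_classes,))
        if np.any(t <= 0) or np.any(t >= 1):
            raise ValueError("thresholds must lie strictly in (0, 1)")
        return t

    def decide(self, probabilities: np.ndarray) -> np.ndarray:
        t = self.thresholds(probabilities.shape[-1])
        return (probabilities >= t).astype(np.int64)


@dataclass
class MetricsBundle:
    precision: float  # macro, percent
    recall: float
    f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_class_ap: np.ndarray  # percent; NaN where AP is undefined
    map: float  # mean over defined classes, percent
    excluded_classes: list[int] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "micro_precision": self.micro_precision,
                "micro_recall": self.micro_recall,
                "micro_f1": self.micro_f1,
                "mAP": self.map,
            }
        )


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2PR/(P+R), on whatever scale P and R share."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def classification_metrics(
    predictions: np.ndarray,
    truths: np.ndarray,
    rule: DecisionRule | None = None,
) -> MetricsBundle:
    """Threshold-based P/R/F1 plus ranking-based per-class AP and mAP.

    ``predictions``: probabilities [n, C]; ``truths``: multi-hot [n, C].
    Classes with zero positives have undefined AP and are excluded from the
    mean with a logged note.
    """
    rule = rule or DecisionRule()
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must align")
    decided = rule.decide(predictions)
    macro_p, macro_r, _, _ = precision_recall_fscore_support(
        truths, decided, average="macro", zero_division=0
    )
    micro_p, micro_r, micro_f, _ = precision_recall_fscore_support(
        truths, decided, average="micro", zero_division=0
    )
    # F1 is the harmonic mean of the reported (macro) precision and recall,
    # so the P/R/F1 triple always satisfies the harmonic-mean identity.
    macro_f = harmonic_f1(macro_p, macro_r)
    n_classes = truths.shape[1]
    ap = np.full(n_classes, np.nan)
    excluded = []
    for c in range(n_classes):
        if truths[:, c].sum() == 0:
            excluded.append(c)
            continue
        ap[c] = 100.0 * average_precision_score(truths[:, c], predictions[:, c])
    if excluded:
        logger.info("AP undefined for zero-positive classes %s; excluded from mAP", excluded)
    mean_ap = float(np.nanmean(ap)) if np.any(~np.isnan(ap)) else float("nan")
    return MetricsBundle(
        precision=100.0 * macro_p,
        recall=100.0 * macro_r,
        f1=100.0 * macro_f,
        micro_precision=100.0 * micro_p,
        micro_recall=100.0 * micro_r,
        micro_f1=100.0 * micro_f,
        per_class_ap=ap,
        map=mean_ap,
        excluded_classes=excluded,
    )


def pair_metrics(
    predictions: np.ndarray,
    truths: np.ndarray,
    pairs,
    rule: DecisionRule | None = None,
    pair_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-pair and macro-averaged P/R/F1 for joint label predictions.

    A pair (i, j) is predicted present in an image iff both probabilities
    clear their class thresholds; it is truly present iff both truth labels
    are 1. Pairs absent from the truth everywhere have undefined recall and
    are reported as NaN, excluded from the macro average. ``pairs`` may be a
    PairSet or an iterable of (i, j). Percentages; last row is the macro
    'Average'.
    """
    rule = rule or DecisionRule()
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths)
    decided = rule.decide(predictions)
    pair_list = list(pairs.pairs) if hasattr(pairs, "pairs") else [tuple(p) for p in pairs]
    rows = []
    for idx, (i, j) in enumerate(pair_list):
        pred = decided[:, i] & decided[:, j]
        true = (truths[:, i] & truths[:, j]).astype(bool)
        tp = int(np.sum(pred & true))
        fp = int(np.sum(pred & ~true))
        fn = int(np.sum(~pred.astype(bool) & true))
        if tp + fn == 0:
            p = r = f = np.nan  # pair never present in truth: not applicable
        else:
            p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
            r = 100.0 * tp / (tp + fn)
            f = harmonic_f1(p, r)
        name = pair_names[idx] if pair_names else f"({i},{j})"
        rows.append({"pair": name, "precision": p, "recall": r, "f1": f,
                     "tp": tp, "fp": fp, "fn": fn})
    df = pd.DataFrame(rows)
    avg = {
        "pair": "Average",
        "precision": df["precision"].mean(skipna=True),
        "recall": df["recall"].mean(skipna=True),
        "f1": df["f1"].mean(skipna=True),
        "tp": df["tp"].sum(),
        "fp": df["fp"].sum(),
        "fn": df["fn"].sum(),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


# ------------------------------------------------- attention localization mAP


def box_iou(a, b) -> float:
    """IoU of two half-open boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = max(0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def _heatmap_box(heatmap: np.ndarray, canvas: int) -> tuple[int, int, int, int] | None:
    """Largest connected component above half the max, scaled to pixels."""
    if heatmap.max() <= 0:
        return None
    mask = heatmap >= 0.5 * heatmap.max()
    labeled, n = ndimage.label(mask)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    comp = 1 + int(np.argmax(sizes))
    ys, xs = np.nonzero(labeled == comp)
    g = heatmap.shape[0]
    cell = canvas / g
    return (
        int(xs.min() * cell),
        int(ys.min() * cell),
        int((xs.max() + 1) * cell),
        int((ys.max() + 1) * cell),
    )


def attention_localization_map(
    heatmaps: np.ndarray,
    probabilities: np.ndarray,
    boxes_per_image: list[list[tuple]],
    canvas: int,
    iou_threshold: float = 0.5,
) -> float:
    """mAP over classes of attention-derived boxes at an IoU threshold.

    For every image and label, the co-attention heatmap is turned into one
    candidate box scored with the label probability; a candidate is a true
    positive when some ground-truth box of that label reaches the IoU
    threshold. AP per class over the ranked candidates, mean over classes
    with ground truth. Returns a percentage.
    """
    n, n_labels = probabilities.shape
    aps = []
    for c in range(n_labels):
        scores, hits = [], []
        n_gt = 0
        for img in range(n):
            gt = [b[1:] for b in boxes_per_image[img] if b[0] == c]
            n_gt += len(gt)
            cand = _heatmap_box(heatmaps[img, c], canvas)
            if cand is None:
                continue
            scores.append(probabilities[img, c])
            hits.append(any(box_iou(cand, g) >= iou_threshold for g in gt))
        if n_gt == 0:
            continue
        if not scores:
            aps.append(0.0)
            continue
        order = np.argsort(scores)[::-1]
        hits_arr = np.asarray(hits)[order]
        tp_cum = np.cumsum(hits_arr)
        precision_at = tp_cum / (np.arange(len(hits_arr)) + 1)
        ap = float(np.sum(precision_at * hits_arr) / n_gt)
        aps.append(100.0 * ap)
    return float(np.mean(aps)) if aps else float("nan")
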