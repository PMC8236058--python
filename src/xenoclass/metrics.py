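"""Evaluation: classification metrics, object-detection matching, feature
correlation, and feature-subset (ablation) masks.

Detection quality uses the instance-segmentation convention: predicted and
ground-truth objects are matched one-to-one by IoU (greedy, descending IoU,
threshold 0.5 by default), then accuracy = TP/(TP+FP+FN), which relates to
precision P and sensitivity R through the identity 1/(1/P + 1/R - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .catalog import SHAPE_NAMES, catalog_names, feature_catalog

__all__ = [
    "ClassMetrics",
    "DetectionMetrics",
    "AblationMask",
    "evaluate_classification",
    "evaluate_detection",
    "accuracy_from_precision_sensitivity",
    "f1_from_precision_sensitivity",
    "correlation_index",
    "ablation_mask",
]


def f1_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def accuracy_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """Detection accuracy TP/(TP+FP+FN) expressed through P and R:
    1 / (1/P + 1/R - 1)."""
    if precision <= 0 or sensitivity <= 0:
        return 0.0
    return 1.0 / (1.0 / precision + 1.0 / sensitivity - 1.0)


@dataclass
class ClassMetrics:
    """Overall accuracy plus per-class precision/sensitivity/F1/AUC-ROC.
    Classes absent from the ground truth report None."""

    accuracy: float
    per_class: dict = field(default_factory=dict)


def evaluate_classification(
    y_true, y_pred, probabilities=None, class_names=None
) -> ClassMetrics:
    """Compute classification metrics.

    ``probabilities`` is an (n, n_classes) array whose columns follow
    ``class_names`` (or the sorted union of observed labels); AUC-ROC is
    one-vs-rest using each class's probability as the score.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between truth and predictions")
    if class_names is None:
        class_names = sorted(set(y_true) | set(y_pred))
    acc = float((y_true == y_pred).mean())
    per_class: dict = {}
    for ci, c in enumerate(class_names):
        if (y_true == c).sum() == 0:
            per_class[c] = None
            continue
        tp = float(((y_pred == c) & (y_true == c)).sum())
        fp = float(((y_pred == c) & (y_true != c)).sum())
        fn = float(((y_pred != c) & (y_true == c)).sum())
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
        entry = {
            "precision": precision,
            "sensitivity": sensitivity,
            "f1": f1_from_precision_sensitivity(precision, sensitivity),
        }
        if probabilities is not None and len(set(y_true)) > 1:
            probs = np.asarray(probabilities)
            entry["auc"] = float(
                roc_auc_score((y_true == c).astype(int), probs[:, ci])
            )
        per_class[c] = entry
    return ClassMetrics(accuracy=acc, per_class=per_class)


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    f1: float


def evaluate_detection(
    pred_labels: np.ndarray, gt_labels: np.ndarray, iou_threshold: float = 0.5
) -> DetectionMetrics:
    """Match predicted to ground-truth objects one-to-one by IoU and count
    TP/FP/FN.

    Matching is greedy on descending IoU (ties broken by label ids), accepting
    pairs with IoU >= threshold. Empty prediction and empty ground truth is
    a perfect (if vacuous) detection: all metrics 1.
    """
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("label rasters differ in shape")
    gt_ids = np.unique(gt_labels)
    gt_ids = gt_ids[gt_ids > 0]
    pred_ids = np.unique(pred_labels)
    pred_ids = pred_ids[pred_ids > 0]
    if len(gt_ids) == 0 and len(pred_ids) == 0:
        return DetectionMetrics(0, 0, 0, 1.0, 1.0, 1.0, 1.0)

    # Pixel-pair contingency between overlapping objects.
    both = (gt_labels > 0) & (pred_labels > 0)
    pairs, counts = np.unique(
        np.stack([gt_labels[both], pred_labels[both]]), axis=1, return_counts=True
    ) if both.any() else (np.zeros((2, 0), dtype=int), np.zeros(0, dtype=int))
    gt_area = {int(g): int((gt_labels == g).sum()) for g in gt_ids}
    pred_area = {int(p): int((pred_labels == p).sum()) for p in pred_ids}

    cand = []
    for (g, p), inter in zip(pairs.T, counts):
        union = gt_area[int(g)] + pred_area[int(p)] - int(inter)
        iou = inter / union
        if iou >= iou_threshold:
            cand.append((iou, int(g), int(p)))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_g: set[int] = set()
    matched_p: set[int] = set()
    tp = 0
    for iou, g, p in cand:
        if g in matched_g or p in matched_p:
            continue
        matched_g.add(g)
        matched_p.add(p)
        tp += 1
    fp = len(pred_ids) - tp
    fn = len(gt_ids) - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
    accuracy = tp / (tp + fp + fn) if tp + fp + fn > 0 else 0.0
    return DetectionMetrics(
        tp,
        fp,
        fn,
        accuracy,
        precision,
        sensitivity,
        f1_from_precision_sensitivity(precision, sensitivity),
    )


def correlation_index(feature_column, class_labels) -> float:
    """|Pearson r| between a feature and the 0/1 class encoding.

    Correlation direction is irrelevant to discriminative power, hence the
    absolute value. Zero-variance features (or degenerate label sets) score 0.
    """
    x = np.asarray(feature_column, dtype=float)
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("correlation index is defined for binary classes")
    if len(x) != len(labels) or len(x) < 2:
        raise ValueError("need >= 2 paired samples")
    y = (labels == classes[1]).astype(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


@dataclass
class AblationMask:
    """Boolean mask over the 484-feature catalog selecting a feature family
    combination (textural on/off x contextual on/off)."""

    include_textural: bool
    include_contextual: bool
    mask: np.ndarray = field(default=None)

    @property
    def names(self) -> list[str]:
        all_names = catalog_names()
        return [n for n, m in zip(all_names, self.mask) if m]


def ablation_mask(include_textural: bool, include_contextual: bool) -> AblationMask:
    """Feature-subset mask for the four ablation combinations.

    * no/no: the 9 shape/size intrinsic features only;
    * yes/no: all 47 intrinsic features;
    * no/yes: shape/size intrinsics plus all contextual features except
      neighbor aggregates of textural (color/Haralick) intrinsics — contextual
      information with no texture content;
    * yes/yes: all 484 features.
    """
    mask = np.zeros(len(catalog_names()), dtype=bool)
    for i, d in enumerate(feature_catalog()):
        if d.category == "intrinsic":
            if d.name in SHAPE_NAMES:
                mask[i] = True
            elif include_textural:
                mask[i] = True
        elif d.category == "organization":
            mask[i] = include_contextual
        else:  # neighbor_derived: kconn{K}_{mean|var}_{intrinsic name}
            if not include_contextual:
                continue
            base = d.name.split("_", 2)[2]
            is_textural = base not in SHAPE_NAMES
            mask[i] = include_textural or not is_textural
    return AblationMask(include_textural, include_contextual, mask)
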