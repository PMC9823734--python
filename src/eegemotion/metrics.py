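"""Confusion matrices and the accuracy / precision / recall / F-measure suite.

Rows of the confusion matrix are true classes, columns predicted, in the
fixed order (negative, neutral, positive).  Per-class precision and recall
are one-vs-rest; the single reported numbers are macro averages (unweighted
means over classes) by default, with micro-averaging available.  Zero
denominators yield 0 with a logged warning, the common reporting convention.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .data_io import CLASS_NAMES

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


@dataclasses.dataclass
class ConfusionMatrix:
    """C×C nonnegative integer counts; counts[i, j] = true i predicted j."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise InputError(f"expected a {c}x{c} matrix")
        if np.any(self.counts < 0):
            raise InputError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class k."""
        c = self.counts
        tp = int(c[k, k])
        fp = int(c[:, k].sum() - c[k, k])
        fn = int(c[k, :].sum() - c[k, k])
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    per_class: dict[str, dict[str, float]]
    averaging: str = "macro"


def confusion_matrix(true_labels: np.ndarray, predicted_labels: np.ndarray,
                     n_classes: int = len(CLASS_NAMES)) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    if true_labels.shape != predicted_labels.shape:
        raise InputError("label vectors must have equal length")
    for arr in (true_labels, predicted_labels):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise InputError("label outside the class set")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (true_labels, predicted_labels), 1)
    return ConfusionMatrix(counts, CLASS_NAMES[:n_classes])


def accuracy(cm: ConfusionMatrix) -> float:
    """Total correct classifications over all evaluated rows."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; returning 0", what)
        return 0.0
    return num / den


def precision(cm: ConfusionMatrix, k: int) -> float:
    """TP / (TP + FP) for one-vs-rest class k."""
    if not 0 <= k < len(cm.class_names):
        raise InputError(f"invalid class index {k}")
    tp, _, fp, _ = cm.one_vs_rest(k)
    return _safe_ratio(tp, tp + fp, f"precision({cm.class_names[k]})")


def recall(cm: ConfusionMatrix, k: int) -> float:
    """TP / (TP + FN): the fraction of class-k rows that were retrieved."""
    if not 0 <= k < len(cm.class_names):
        raise InputError(f"invalid class index {k}")
    tp, _, _, fn = cm.one_vs_rest(k)
    return _safe_ratio(tp, tp + fn, f"recall({cm.class_names[k]})")


def f_measure(pr: float, rc: float) -> float:
    """Harmonic mean 2·Pr·Rc/(Pr+Rc); 0 when both are 0."""
    if pr == 0.0 and rc == 0.0:
        return 0.0
    return 2.0 * pr * rc / (pr + rc)


def macro_report(cm: ConfusionMatrix, averaging: str = "macro") -> MetricsReport:
    """Per-class one-vs-rest metrics plus the averaged summary row.

    macro: unweighted mean of per-class precision/recall/F.
    micro: pooled TP/FP/FN over classes (equals accuracy for single-label
    multiclass data).
    """
    if averaging not in ("macro", "micro"):
        raise InputError(f"unknown averaging {averaging!r}")
    per_class: dict[str, dict[str, float]] = {}
    prs, rcs, fms = [], [], []
    tps = fps = fns = 0
    for k, name in enumerate(cm.class_names):
        tp, tn, fp, fn = cm.one_vs_rest(k)
        pr, rc = precision(cm, k), recall(cm, k)
        fm = f_measure(pr, rc)
        per_class[name] = {"precision": pr, "recall": rc, "f_measure": fm,
                           "tp": tp, "tn": tn, "fp": fp, "fn": fn}
        prs.append(pr); rcs.append(rc); fms.append(fm)
        tps += tp; fps += fp; fns += fn
    if averaging == "macro":
        pr_avg, rc_avg = float(np.mean(prs)), float(np.mean(rcs))
        fm_avg = float(np.mean(fms))
    else:
        pr_avg = _safe_ratio(tps, tps + fps, "micro precision")
        rc_avg = _safe_ratio(tps, tps + fns, "micro recall")
        fm_avg = f_measure(pr_avg, rc_avg)
    return MetricsReport(accuracy(cm), pr_avg, rc_avg, fm_avg, per_class, averaging)
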