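"""Binary-classification metrics: SN/SP/PRE/ACC/F-score/MCC and trapezoidal AUC.

Positives are coding transcripts.  MCC uses the square-rooted four-factor
denominator so it is bounded by [-1, 1].  AUC integrates the ROC curve with
the trapezoid rule, stepping through descending score thresholds and
collapsing tied scores into a single ROC point (which makes it equal to the
rank-sum / Mann-Whitney formulation with ties counted half).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

POSITIVE = "coding"
NEGATIVE = "noncoding"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class EvalMetrics:
    SN: float
    SP: float
    PRE: float
    ACC: float
    F_score: float
    MCC: float
    AUC: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("SN", "SP", "PRE", "ACC", "F_score", "MCC", "AUC")}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as 0", what)
        return 0.0
    return num / den


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN with coding as the positive class."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred, strict=True):
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def roc_auc(scores, y_true) -> float:
    """Trapezoidal area under the ROC curve of coding scores.

    Tied scores form one ROC point, so ties contribute half their area —
    identical to the Mann-Whitney U formulation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([1 if t == POSITIVE else 0 for t in y_true])
    P = int(labels.sum())
    N = len(labels) - P
    if P == 0 or N == 0:
        logger.warning("AUC undefined with a single class; reported as 0")
        return 0.0
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    auc = 0.0
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        d_tp = int(labels[i:j].sum())
        d_fp = (j - i) - d_tp
        prev_tpr, prev_fpr = tp / P, fp / N
        tp += d_tp
        fp += d_fp
        auc += (fp / N - prev_fpr) * (tp / P + prev_tpr) / 2.0
        i = j
    return auc


def compute_metrics(counts: ConfusionCounts, scores) -> EvalMetrics:
    """Metric bundle from confusion counts plus (coding_probability, label) pairs."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on an empty evaluation set")
    if len(scores) != counts.total:
        raise ValueError("scores length inconsistent with confusion counts")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sn = _safe_div(tp, tp + fn, "SN")
    sp = _safe_div(tn, fp + tn, "SP")
    pre = _safe_div(tp, tp + fp, "PRE")
    acc = _safe_div(tp + tn, counts.total, "ACC")
    f_score = _safe_div(2 * pre * sn, pre + sn, "F-score")
    mcc_den = math.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    auc = roc_auc([s for s, _ in scores], [t for _, t in scores])
    return EvalMetrics(sn, sp, pre, acc, f_score, mcc, auc)


def evaluate_predictions(y_true, y_pred, coding_probs) -> EvalMetrics:
    """Convenience wrapper: confusion counts + metric bundle in one call."""
    counts = confusion_from_predictions(y_true, y_pred)
    return compute_metrics(counts, list(zip(coding_probs, y_true)))
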