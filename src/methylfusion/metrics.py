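"""Binary classification assessment: SN, SP, ACC, MCC, ROC/AUC and PR/AP.

Positive class is "methylated" (label 1). MCC is reported as 0 (and
flagged) when any factor of its denominator vanishes, where the formula is
undefined. ROC and PR curves sweep thresholds over the unique score values
with ties grouped, so the trapezoidal AUC equals the Mann-Whitney
probability that a random positive outranks a random negative with ties
credited 1/2; AP is the step-wise sum Σ (R_i − R_{i−1}) P_i.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "compute_metrics", "roc_pr", "evaluate_predictions"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    ap: float | None = None
    mcc_undefined: bool = False
    roc_points: np.ndarray | None = field(default=None, repr=False)
    pr_points: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        out = {"TP": self.counts.tp, "TN": self.counts.tn,
               "FP": self.counts.fp, "FN": self.counts.fn,
               "SN": self.sn, "SP": self.sp, "ACC": self.acc,
               "MCC": self.mcc}
        if self.auc is not None:
            out["AUC"] = self.auc
        if self.ap is not None:
            out["AP"] = self.ap
        return out

    def save(self, path: str | Path) -> None:
        """Flat key-value CSV."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for key, value in self.as_dict().items():
                writer.writerow([key, value])


def _validate_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0 and 1")
    return arr.astype(np.int64)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    yt = _validate_binary(y_true, "y_true")
    yp = _validate_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(
            f"length mismatch: {yt.shape[0]} labels vs {yp.shape[0]} predictions")
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tn + fp) * (fp + tp) * (tp + fn) * (tn + fn)
    undefined = denom == 0
    mcc = 0.0 if undefined else ((tn * tp) - (fn * fp)) / np.sqrt(denom)
    return MetricsReport(counts=counts, sn=float(sn), sp=float(sp),
                         acc=float(acc), mcc=float(mcc),
                         mcc_undefined=undefined)


def roc_pr(y_true, scores) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Threshold sweep over unique scores (ties grouped).

    Returns (roc_points [FPR, TPR], AUC, pr_points [recall, precision], AP).
    """
    yt = _validate_binary(y_true, "y_true")
    sc = np.asarray(scores, dtype=float)
    if sc.shape != yt.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(sc)):
        raise ValueError("scores must be finite")
    n_pos = int(yt.sum())
    n_neg = int(yt.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to draw ROC/PR curves")

    order = np.argsort(-sc, kind="stable")
    sc_sorted = sc[order]
    yt_sorted = yt[order]
    # indices where a tie group of scores ends
    distinct = np.nonzero(np.diff(sc_sorted))[0]
    cut = np.r_[distinct, yt_sorted.size - 1]
    tp = np.cumsum(yt_sorted)[cut].astype(float)
    fp = np.cumsum(1 - yt_sorted)[cut].astype(float)

    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))

    recall = tp / n_pos
    precision = tp / (tp + fp)
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))

    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([np.r_[0.0, recall],
                                 np.r_[1.0, precision]])
    return roc_points, auc, pr_points, ap


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report from probabilities: counts at ``threshold`` plus AUC/AP."""
    yt = _validate_binary(y_true, "y_true")
    sc = np.asarray(scores, dtype=float)
    y_pred = (sc >= threshold).astype(np.int64)
    base = compute_metrics(confusion_counts(yt, y_pred))
    roc_points, auc, pr_points, ap = roc_pr(yt, sc)
    return MetricsReport(counts=base.counts, sn=base.sn, sp=base.sp,
                         acc=base.acc, mcc=base.mcc, auc=auc, ap=ap,
                         mcc_undefined=base.mcc_undefined,
                         roc_points=roc_points, pr_points=pr_points)


def save_curve(points: np.ndarray, path: str | Path, header: tuple[str, str]) -> None:
    """ROC or PR point list as two-column CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(points.tolist())
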