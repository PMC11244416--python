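"""Imbalance-aware classification metrics and ERP significance windows.

With a 1:4 positive:negative trial ratio, plain accuracy rewards majority-class
collapse; evaluation therefore centers on balanced accuracy (the mean of the
true-positive and true-negative rates), the F1 score, and the rank-based AUC.
Ratios with a zero denominator are reported as ``nan`` (undefined) with a
warning rather than silently as zero, so degenerate folds cannot inflate
aggregates.

The module also provides the pointwise paired t-test procedure used to locate
time windows where two ERP conditions differ: a two-sided paired t-test at
every sample, with maximal runs of consecutively significant samples returned
as half-open windows (no multiplicity correction).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = ["ConfusionCounts", "EvalReport", "confusion_counts",
           "classification_metrics", "auc", "significant_windows",
           "evaluate_predictions", "aggregate_reports", "write_report"]


class ConfusionCounts(NamedTuple):
    TP: int
    FP: int
    TN: int
    FN: int


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Four-cell confusion counts for binary labels (positive class = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot count an empty prediction set")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.all(np.isin(arr, (0, 1))):
            raise ValueError(f"{name} must be binary (0 or 1)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reporting nan",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """TPR, TNR, FPR, precision, recall, BA and F1 from confusion counts.

    BA = (TPR + TNR) / 2; F1 = 2 * precision * recall / (precision + recall).
    Any ratio whose denominator is zero is nan with a warning.
    """
    tp, fp, tn, fn = counts
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("confusion counts are all zero")
    tpr = _ratio(tp, tp + fn, "TPR")
    tnr = _ratio(tn, fp + tn, "TNR")
    fpr = _ratio(fp, fp + tn, "FPR")
    precision = _ratio(tp, tp + fp, "precision")
    recall = tpr
    ba = (tpr + tnr) / 2.0
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        if not (np.isnan(precision) or np.isnan(recall)):
            warnings.warn("F1 is undefined (precision + recall = 0); reporting nan",
                          RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"TPR": tpr, "TNR": tnr, "FPR": fpr, "precision": precision,
            "recall": recall, "BA": ba, "F1": f1}


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Estimates the probability that a randomly drawn positive outscores a
    randomly drawn negative, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = stats.rankdata(scores)  # midranks
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def significant_windows(condition_a: np.ndarray, condition_b: np.ndarray,
                        alpha: float = 0.05, min_run_length: int = 1,
                        ) -> List[Tuple[int, int]]:
    """Pointwise paired t-test between two conditions' per-subject average ERPs.

    Both inputs have shape (n_subjects, T) and are paired by row (the same
    subject measured under both conditions).  A two-sided paired t-test is run
    at every time point; maximal runs of at least ``min_run_length``
    consecutive points with p < alpha are returned as half-open sample windows
    ``(start, end)``.  Time points with zero within-pair variance have an
    undefined p-value and are treated as non-significant, with a warning.
    No multiple-comparison correction is applied.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must be equal-shape (n_subjects, T) arrays")
    if a.shape[0] < 2:
        raise ValueError("need at least two subjects for a paired t-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on zero-variance columns
        _, p = stats.ttest_rel(a, b, axis=0)
    # zero within-pair variance makes the t statistic undefined even when the
    # mean difference is nonzero; such points are declared non-significant
    undefined = ~np.isfinite(p) | ((a - b).std(axis=0) == 0)
    if np.any(undefined):
        warnings.warn(
            f"{int(undefined.sum())} time points have undefined p-values "
            "(zero within-pair variance); treated as non-significant",
            RuntimeWarning, stacklevel=2)
    sig = np.where(undefined, False, p < alpha)
    windows: List[Tuple[int, int]] = []
    start = None
    for t, s in enumerate(sig):
        if s and start is None:
            start = t
        elif not s and start is not None:
            if t - start >= min_run_length:
                windows.append((start, t))
            start = None
    if start is not None and len(sig) - start >= min_run_length:
        windows.append((start, len(sig)))
    return windows


@dataclass
class EvalReport:
    """Confusion counts plus derived metrics, optionally aggregated over folds."""

    TP: int
    FP: int
    TN: int
    FN: int
    TPR: float
    TNR: float
    FPR: float
    precision: float
    recall: float
    BA: float
    F1: float
    AUC: Optional[float] = None
    per_fold: List["EvalReport"] = field(default_factory=list)
    summary: Optional[Dict[str, Tuple[float, float]]] = None  # metric -> (mean, sd)

    METRIC_FIELDS = ("TPR", "TNR", "FPR", "precision", "recall", "BA", "F1", "AUC")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("TP", "FP", "TN", "FN") + self.METRIC_FIELDS}
        if self.per_fold:
            d["per_fold"] = [r.to_dict() for r in self.per_fold]
        if self.summary is not None:
            d["summary"] = {k: {"mean": m, "sd": s}
                            for k, (m, s) in self.summary.items()}
        return d


def evaluate_predictions(y_true: Sequence[int], y_pred: Sequence[int],
                         scores: Optional[Sequence[float]] = None) -> EvalReport:
    """Build an :class:`EvalReport` from labels, predictions and (optionally) scores."""
    counts = confusion_counts(y_true, y_pred)
    m = classification_metrics(counts)
    a = auc(scores, y_true) if scores is not None else None
    return EvalReport(TP=counts.TP, FP=counts.FP, TN=counts.TN, FN=counts.FN,
                      AUC=a, **m)


def aggregate_reports(reports: Sequence[EvalReport]) -> EvalReport:
    """Pool per-fold reports: summed counts, pooled metrics, mean +/- sd per fold."""
    if not reports:
        raise ValueError("no reports to aggregate")
    counts = ConfusionCounts(sum(r.TP for r in reports), sum(r.FP for r in reports),
                             sum(r.TN for r in reports), sum(r.FN for r in reports))
    m = classification_metrics(counts)
    summary = {}
    for name in EvalReport.METRIC_FIELDS:
        vals = np.array([getattr(r, name) for r in reports
                         if getattr(r, name) is not None], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals):
            summary[name] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    aucs = [r.AUC for r in reports if r.AUC is not None]
    pooled_auc = float(np.mean(aucs)) if aucs else None
    return EvalReport(TP=counts.TP, FP=counts.FP, TN=counts.TN, FN=counts.FN,
                      AUC=pooled_auc, per_fold=list(reports), summary=summary, **m)


def write_report(report: EvalReport, path: str) -> None:
    """Serialize a report as JSON (``.json``) or per-fold CSV rows (``.csv``)."""
    if path.endswith(".json"):
        with open(path, "w") as f:
            json.dump(report.to_dict(), f, indent=2, default=float)
        return
    if path.endswith(".csv"):
        import pandas as pd

        rows = [r.to_dict() for r in (report.per_fold or [report])]
        for row in rows:
            row.pop("per_fold", None)
            row.pop("summary", None)
        df = pd.DataFrame(rows)
        df.index.name = "fold"
        df.to_csv(path)
        return
    raise ValueError("report path must end in .json or .csv")
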