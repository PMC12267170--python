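"""Diagnostic evaluation: confusion statistics, ROC/AUROC with Youden
threshold, precision-recall / average precision, and Cohen's kappa.

Multi-class metrics are computed one-vs-rest per class and macro-averaged;
AUROC equals the rank statistic (probability a random positive outscores a
random negative, ties counted one half), which the trapezoid ROC area
reproduces exactly.  The macro average over per-class average precision is
exposed as ``map_macro`` — the classification analogue of a detection mAP,
named so as not to imply any box-overlap criterion.

A class absent from the truth has undefined recall: it is reported as NaN
(missing), never as zero, and macro averages skip missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .errors import MetricsError


@dataclass
class MetricsReport:
    """Per-class and macro diagnostic metrics for one evaluation."""

    labels: list
    accuracy: float
    per_class: pd.DataFrame  # rows: class; cols: sensitivity, specificity, precision, f1, auroc, ap
    macro: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict[str, float]:
        row = {"accuracy": self.accuracy}
        row.update({k: v for k, v in self.macro.items()})
        return row


def confusion_counts(y_true, y_pred, labels: Sequence) -> np.ndarray:
    """K x K counts, rows = truth, columns = prediction."""
    return skm.confusion_matrix(y_true, y_pred, labels=list(labels))


def confusion_metrics(y_true, y_pred, labels: Sequence) -> MetricsReport:
    """Threshold-free confusion statistics.

    Per-class one-vs-rest sensitivity (recall), specificity, precision and
    F1, plus macro averages and overall accuracy.  Classes absent from the
    truth get NaN recall/F1; classes never predicted get NaN precision.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise MetricsError("empty input")
    if len(y_true) != len(y_pred):
        raise MetricsError("length mismatch")
    cm = confusion_counts(y_true, y_pred, labels)
    total = cm.sum()
    rows = {}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        prec = tp / (tp + fp) if tp + fp else np.nan
        f1 = (
            2 * prec * sens / (prec + sens)
            if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
            else (0.0 if np.isfinite(prec) and np.isfinite(sens) else np.nan)
        )
        rows[lab] = {"sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    macro = {f"{c}_macro": float(np.nanmean(per_class[c])) for c in per_class.columns}
    return MetricsReport(
        labels=list(labels),
        accuracy=float(np.trace(cm) / total),
        per_class=per_class,
        macro=macro,
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Binary ROC curve and trapezoid area.

    ``labels`` are 0/1; ``scores`` are real-valued.  Ties are grouped at a
    single threshold, so the trapezoid area equals the Mann-Whitney rank
    statistic with ties counted one half.

    Returns ``(fpr, tpr, thresholds, auc)``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise MetricsError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    return fpr, tpr, thr, float(skm.auc(fpr, tpr))


def youden_threshold(
    fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray
) -> tuple[float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties resolve to the lowest threshold.  The leading ``inf`` threshold
    emitted by the curve construction (no positives predicted) is a valid
    candidate but can never win a tie against a finite threshold.
    """
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # thresholds are sorted descending; the last tied index is the lowest
    idx = int(best[-1])
    return float(thresholds[idx]), float(j[idx])


def average_precision(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Binary PR curve and step-interpolated average precision.

    AP = sum over descending-score prefixes of (R_k - R_{k-1}) * P_k.
    Returns ``(precision, recall, ap)``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise MetricsError("average precision needs at least one positive")
    precision, recall, _ = skm.precision_recall_curve(labels, scores)
    ap = float(skm.average_precision_score(labels, scores))
    return precision, recall, ap


def cohen_kappa(rater_a, rater_b) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Returns NaN when the marginals are degenerate (p_e == 1), in which
    case agreement beyond chance is undefined.
    """
    a, b = np.asarray(rater_a), np.asarray(rater_b)
    if len(a) != len(b):
        raise MetricsError("raters must score the same cases")
    if len(a) == 0:
        raise MetricsError("empty input")
    labels = sorted(set(a) | set(b))
    if len(labels) == 1:  # both raters constant and identical: p_e = 1
        return float("nan")
    cm = skm.confusion_matrix(a, b, labels=labels).astype(float)
    n = cm.sum()
    pe = float((cm.sum(0) / n) @ (cm.sum(1) / n))
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return float(skm.cohen_kappa_score(a, b, labels=labels))


def evaluate_scores(
    y_true, proba: np.ndarray, labels: Sequence
) -> MetricsReport:
    """Full report from per-class probability scores.

    Combines confusion statistics at the argmax prediction with one-vs-rest
    AUROC and AP per class and their macro means.  Classes missing from the
    truth (or single-class after binarisation) get NaN curve metrics.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba)
    y_pred = np.asarray(list(labels))[proba.argmax(axis=1)]
    report = confusion_metrics(y_true, y_pred, labels)
    aurocs, aps = [], []
    for i, lab in enumerate(labels):
        bin_true = (y_true == lab).astype(int)
        if 0 < bin_true.sum() < len(bin_true):
            _, _, _, auc_i = roc_auc(proba[:, i], bin_true)
            _, _, ap_i = average_precision(proba[:, i], bin_true)
        else:
            auc_i, ap_i = np.nan, np.nan
        aurocs.append(auc_i)
        aps.append(ap_i)
    report.per_class["auroc"] = aurocs
    report.per_class["ap"] = aps
    report.macro["auroc_macro"] = float(np.nanmean(aurocs))
    report.macro["map_macro"] = float(np.nanmean(aps))
    return report


def report_table(reports_by_scenario: dict[str, list[MetricsReport]]) -> pd.DataFrame:
    """Assemble a comparison table: one row per scenario, ``mean (SD)``
    strings per metric across repeats — the published table's schema."""
    cols = [
        "accuracy",
        "sensitivity_macro",
        "specificity_macro",
        "precision_macro",
        "f1_macro",
        "auroc_macro",
    ]
    rows = {}
    for scenario, reports in reports_by_scenario.items():
        frame = pd.DataFrame([r.to_row() for r in reports])
        row = {}
        for c in cols:
            if c not in frame:
                continue
            mean, sd = frame[c].mean(), frame[c].std(ddof=1) if len(frame) > 1 else 0.0
            row[c] = f"{mean:.3f} ({sd:.3f})"
        rows[scenario] = row
    return pd.DataFrame.from_dict(rows, orient="index")
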