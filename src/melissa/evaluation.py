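"""Imputation and clustering metrics.

All metrics are pure functions of their inputs.  AUC uses midrank tie
handling (the Mann-Whitney pair statistic), so a constant predictor scores
exactly 0.5.  Conventions for empty denominators: precision is 0 when
nothing is predicted positive, and the F-measure is 0 when precision and
recall are both 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import rankdata

__all__ = [
    "roc_auc",
    "f_measure",
    "adjusted_rand_index",
    "precision_recall_curve",
    "MetricsReport",
    "evaluate_predictions",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels.astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via rank summation.

    Equals the pair statistic P(score+ > score-) + 0.5 P(tie); undefined
    (raises) when only one class is present.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def f_measure(pred_states, labels) -> tuple[float, float, float]:
    """(precision, recall, F1) — the harmonic mean of precision and recall."""
    labels = _check_binary(labels)
    pred = _check_binary(pred_states)
    if pred.shape != labels.shape:
        raise ValueError("shape mismatch")
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions.

    Computed from the contingency table (n_ij) with marginals (a_i, b_j):
    ARI = (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) and
    max = [sum_i C(a_i,2) + sum_j C(b_j,2)] / 2.  Symmetric and invariant
    to label renaming; 1 for identical partitions.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-d arrays")
    n = a.size
    if n < 2:
        raise ValueError("ARI needs at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def precision_recall_curve(scores, labels) -> list[tuple[float, float]]:
    """(recall, precision) points, one per distinct threshold, descending.

    A point classifies as positive every score >= its threshold, so recall
    is non-decreasing along the returned curve.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("precision-recall curve undefined: one class only")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp_cum = np.cumsum(sorted_labels)
    pred_cum = np.arange(1, labels.size + 1)
    # last index of each run of equal scores = classify-at-threshold point
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    curve = []
    for i in np.flatnonzero(distinct):
        precision = tp_cum[i] / pred_cum[i]
        recall = tp_cum[i] / n_pos
        curve.append((float(recall), float(precision)))
    return curve


@dataclass
class MetricsReport:
    """Bundle of imputation (and optionally clustering) metrics."""

    auc: float
    precision: float
    recall: float
    f_measure: float
    counts: dict
    pr_curve: list = field(default_factory=list)
    ari: float | None = None

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "counts": self.counts,
            "pr_curve": self.pr_curve,
        }
        if self.ari is not None:
            d["ari"] = self.ari
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate_predictions(
    predictions: pd.DataFrame,
    labels_true=None,
    labels_pred=None,
    with_curve: bool = False,
) -> MetricsReport:
    """Score a prediction frame (columns ``prob, pred_state, true_state``).

    Pass two label vectors to additionally report the ARI of a clustering.
    """
    y = predictions["true_state"].to_numpy().astype(int)
    prob = predictions["prob"].to_numpy()
    pred = predictions["pred_state"].to_numpy().astype(int)
    precision, recall, f1 = f_measure(pred, y)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    report = MetricsReport(
        auc=roc_auc(prob, y),
        precision=precision,
        recall=recall,
        f_measure=f1,
        counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        pr_curve=precision_recall_curve(prob, y) if with_curve else [],
        ari=(
            adjusted_rand_index(labels_true, labels_pred)
            if labels_true is not None and labels_pred is not None
            else None
        ),
    )
    return report
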