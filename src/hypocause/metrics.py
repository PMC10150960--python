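"""Per-class classification metrics for imbalanced problems.

Everything is computed from one-vs-rest confusion counts: precision, recall,
their harmonic mean F1, and the Matthews correlation coefficient (MCC).
Zero-denominator conventions: precision/recall/F1 are 0 when undefined and
MCC is 0 when any confusion-matrix marginal is zero (the constant-predictor
case). Multiclass summaries use unweighted class averages (macro).
"""

from __future__ import annotations

import numpy as np

__all__ = ["confusion_counts", "f1_recall_precision", "mcc", "evaluate_metrics", "class_weights"]


def confusion_counts(y_true, y_pred, positive) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for the one-vs-rest problem of class ``positive``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    t = y_true == positive
    p = y_pred == positive
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return tp, fp, fn, tn


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom2))


def f1_recall_precision(y_true, y_pred, classes) -> dict:
    """Per-class dict of {precision, recall, f1} (one-vs-rest)."""
    out = {}
    for c in classes:
        tp, fp, fn, _ = confusion_counts(y_true, y_pred, c)
        precision, recall, f1 = _prf(tp, fp, fn)
        out[c] = {"precision": precision, "recall": recall, "f1": f1}
    return out


def evaluate_metrics(y_true, y_pred, classes) -> dict:
    """Per-class precision/recall/F1/MCC plus their macro averages."""
    per_class = {}
    for c in classes:
        tp, fp, fn, tn = confusion_counts(y_true, y_pred, c)
        precision, recall, f1 = _prf(tp, fp, fn)
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "mcc": mcc(tp, fp, fn, tn),
        }
    macro = {
        m: float(np.mean([per_class[c][m] for c in classes]))
        for m in ("precision", "recall", "f1", "mcc")
    }
    return {"per_class": per_class, "macro": macro}


def class_weights(labels) -> dict:
    """Inverse-frequency observation weights w_i = N_obs / (N_cl * N_obs_i).

    Balanced classes get weight 1 and the weights of all observations sum to
    N_obs exactly. Raises on an empty label vector."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty label vector")
    classes, counts = np.unique(labels, return_counts=True)
    n_obs, n_cl = len(labels), len(classes)
    return {c: n_obs / (n_cl * k) for c, k in zip(classes, counts)}
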