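"""Presence-absence model evaluation: AUC, Cohen's kappa, TSS.

AUC is computed as the normalised Mann-Whitney U statistic (ties count 0.5);
kappa and TSS are computed from a 2x2 confusion matrix taken at the
probability threshold that maximises TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_matrix_2x2(pred, labels) -> dict:
    """Counts at a fixed prediction: dict with tp, fn, fp, tn."""
    pred = _check_binary(pred)
    labels = _check_binary(labels)
    return {
        "tp": int(np.sum((pred == 1) & (labels == 1))),
        "fn": int(np.sum((pred == 0) & (labels == 1))),
        "fp": int(np.sum((pred == 1) & (labels == 0))),
        "tn": int(np.sum((pred == 0) & (labels == 0))),
    }


def kappa(confusion: dict) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e); 0 (with warning) when p_e = 1."""
    tp, fn, fp, tn = (confusion[k] for k in ("tp", "fn", "fp", "tn"))
    total = tp + fn + fp + tn
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = (tp + tn) / total
    p_yes = ((tp + fn) / total) * ((tp + fp) / total)
    p_no = ((fp + tn) / total) * ((fn + tn) / total)
    p_e = p_yes + p_no
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("kappa undefined (expected agreement = 1); returning 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def tss(confusion: dict) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    tp, fn, fp, tn = (confusion[k] for k in ("tp", "fn", "fp", "tn"))
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("TSS requires both classes present")
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    return float(sens + spec - 1.0)


def max_tss_threshold(scores, labels) -> float:
    """Probability threshold maximising TSS (prediction = score >= threshold).

    Candidate thresholds are the unique scores; ties broken toward the lowest
    threshold for determinism.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    best_t, best_tss = None, -np.inf
    for t in np.unique(scores):
        c = confusion_matrix_2x2((scores >= t).astype(int), labels)
        value = tss(c)
        if value > best_tss + 1e-12:
            best_t, best_tss = t, value
    return float(best_t)


def evaluate_at_max_tss(scores, labels) -> dict:
    """AUC plus kappa/TSS and the confusion matrix at the max-TSS threshold."""
    t = max_tss_threshold(scores, labels)
    c = confusion_matrix_2x2((np.asarray(scores) >= t).astype(int), labels)
    return {
        "auc": auc(scores, labels),
        "kappa": kappa(c),
        "tss": tss(c),
        "threshold": t,
        "confusion": c,
    }


@dataclass
class EvaluationReport:
    """Cross-validation metrics: one row per fold plus pooled values."""

    fold_metrics: pd.DataFrame
    pooled: dict
    excluded_folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "folds": self.fold_metrics.to_dict(orient="records"),
            "pooled": self.pooled,
            "excluded_folds": list(self.excluded_folds),
        }

    def __str__(self) -> str:  # human-readable table
        lines = [self.fold_metrics.to_string(index=False), "", "pooled:"]
        lines += [f"  {k}: {v:.4f}" for k, v in self.pooled.items() if isinstance(v, float)]
        return "\n".join(lines)
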