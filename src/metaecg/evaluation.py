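"""Classification metrics, geometric-mean thresholding and bootstrap CIs.

Scores are probabilities of the VA class (class 1).  ROC-AUC is the
probability that a positive window outranks a negative one (ties counted
half); PR-AUC uses the step-wise average-precision construction.  The
decision threshold for accuracy/F1/balanced accuracy maximizes the geometric
mean of sensitivity and specificity — fitted on a subject's validation part
and applied to its test part, never fitted on test.  Confidence intervals
for macro (across-subject) means come from a subject-level percentile
bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score,
                             balanced_accuracy_score, f1_score,
                             roc_auc_score)

__all__ = ["ScoredSet", "roc_auc", "pr_auc", "gmean_threshold",
           "f1_acc_bacc", "bootstrap_ci", "evaluate_subject", "macro_report"]


@dataclass
class ScoredSet:
    """Per-segment scores and labels for one subject."""
    subject_id: str
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")

    def both_classes(self) -> bool:
        return 0 in self.labels and 1 in self.labels


def _require_both(scored: ScoredSet, what: str):
    if not scored.both_classes():
        raise ValueError(f"{what} undefined: only one class present for "
                         f"subject {scored.subject_id}")


def roc_auc(scored: ScoredSet) -> float:
    _require_both(scored, "ROC-AUC")
    return float(roc_auc_score(scored.labels, scored.scores))


def pr_auc(scored: ScoredSet) -> float:
    _require_both(scored, "PR-AUC")
    return float(average_precision_score(scored.labels, scored.scores))


def gmean_threshold(scored: ScoredSet) -> float:
    """Threshold maximizing sqrt(sensitivity x specificity).

    Candidates are the midpoints between consecutive distinct sorted scores
    plus -inf/+inf sentinels (predict 1 when score > threshold); ties are
    broken toward the smaller threshold.
    """
    _require_both(scored, "gmean threshold")
    s = np.unique(scored.scores)
    candidates = np.concatenate([[-np.inf], (s[:-1] + s[1:]) / 2.0, [np.inf]])
    pos = scored.labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_t, best_g = None, -1.0
    for t in candidates:
        pred = scored.scores > t
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        g = np.sqrt(sens * spec)
        if g > best_g:           # strict: ties keep the smaller threshold
            best_g, best_t = g, t
    return float(best_t)


def f1_acc_bacc(scored: ScoredSet, threshold: float
                ) -> tuple[float, float, float]:
    """(F1, accuracy, balanced accuracy) at a fixed threshold; VA (class 1)
    is the positive class.  A zero-denominator F1 is reported as 0."""
    pred = (scored.scores > threshold).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = float(f1_score(scored.labels, pred, zero_division=0))
    acc = float(accuracy_score(scored.labels, pred))
    bacc = float(balanced_accuracy_score(scored.labels, pred))
    return f1, acc, bacc


def bootstrap_ci(values, n_resamples: int = 20000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the macro mean of per-subject values."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate_subject(test: ScoredSet, validation: ScoredSet | None = None
                     ) -> dict:
    """All metrics for one subject; the threshold is fitted on the
    validation scores when provided (leakage-safe), else on the test set
    itself (flagged in the result)."""
    thr_source = validation if validation is not None else test
    thr = gmean_threshold(thr_source)
    f1, acc, bacc = f1_acc_bacc(test, thr)
    return {"subject_id": test.subject_id,
            "roc_auc": roc_auc(test), "pr_auc": pr_auc(test),
            "f1": f1, "acc": acc, "balanced_acc": bacc,
            "threshold": thr,
            "threshold_fit_on": "validation" if validation is not None
            else "test"}


_METRICS = ("roc_auc", "pr_auc", "f1", "acc", "balanced_acc")


def macro_report(per_subject: list[dict], n_resamples: int = 20000,
                 seed: int = 0, with_ci: bool = True) -> dict:
    """Across-subject macro means (order-invariant) with bootstrap CIs."""
    report = {"per_subject": per_subject, "macro": {}}
    for m in _METRICS:
        vals = [r[m] for r in per_subject]
        entry = {"mean": float(np.mean(vals))}
        if with_ci and len(vals) >= 2:
            entry["ci"] = bootstrap_ci(vals, n_resamples=n_resamples,
                                       seed=seed)
        report["macro"][m] = entry
    return report
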