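"""Metric implementations against brute-force oracles on small inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaecg.evaluation import (ScoredSet, bootstrap_ci, evaluate_subject,
                                f1_acc_bacc, gmean_threshold, macro_report,
                                pr_auc, roc_auc)


def _scored(scores, labels, sid="s"):
    return ScoredSet(sid, np.asarray(scores, float), np.asarray(labels, int))


def _random_scored(rng, n, ties=False):
    scores = rng.integers(0, 10, size=n) / 10.0 if ties else rng.random(n)
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    return _scored(scores, labels)


# ----------------------------------------------------------- oracle helpers

def _auc_oracle(s):
    pos = s.scores[s.labels == 1]
    neg = s.scores[s.labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def _ap_oracle(s):
    """Step-wise average precision: sum over positives, in descending score
    order, of (recall increment) x (precision at that cut)."""
    order = np.argsort(-s.scores, kind="stable")
    labels = s.labels[order]
    scores = s.scores[order]
    n_pos = labels.sum()
    ap, tp = 0.0, 0
    for k in range(len(labels)):
        # evaluate only at distinct-score boundaries (ties share a cut)
        if k + 1 < len(labels) and scores[k + 1] == scores[k]:
            continue
        tp_here = labels[: k + 1].sum()
        recall_prev = (tp / n_pos)
        recall_here = tp_here / n_pos
        precision_here = tp_here / (k + 1)
        ap += (recall_here - recall_prev) * precision_here
        tp = tp_here
    return ap


def _confusion_oracle(s, thr):
    pred = s.scores > thr
    tp = int((pred & (s.labels == 1)).sum())
    fp = int((pred & (s.labels == 0)).sum())
    fn = int((~pred & (s.labels == 1)).sum())
    tn = int((~pred & (s.labels == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * sens / (prec + sens)) if prec + sens else 0.0
    acc = (tp + tn) / len(s.labels)
    return f1, acc, (sens + spec) / 2


# ------------------------------------------------------------------ ROC/PR

def test_perfect_and_tied_rankings():
    assert roc_auc(_scored([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])) == 1.0
    assert roc_auc(_scored([0.5] * 6, [0, 1, 0, 1, 0, 1])) == 0.5


def test_single_class_raises():
    with pytest.raises(ValueError):
        roc_auc(_scored([0.1, 0.2], [1, 1]))
    with pytest.raises(ValueError):
        pr_auc(_scored([0.1, 0.2], [0, 0]))
    with pytest.raises(ValueError):
        gmean_threshold(_scored([0.1, 0.2], [0, 0]))


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("ties", [False, True])
def test_auc_and_ap_match_pair_counting_oracles(seed, ties):
    rng = np.random.default_rng(seed)
    s = _random_scored(rng, 20, ties=ties)
    assert roc_auc(s) == pytest.approx(_auc_oracle(s), abs=1e-12)
    assert pr_auc(s) == pytest.approx(_ap_oracle(s), abs=1e-12)


# ----------------------------------------------------------- gmean threshold

def test_separated_scores_give_perfect_operating_point():
    s = _scored([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], [0, 0, 0, 1, 1, 1])
    thr = gmean_threshold(s)
    f1, acc, bacc = f1_acc_bacc(s, thr)
    assert f1 == acc == bacc == 1.0
    assert 0.3 < thr < 0.7


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_gmean_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    s = _random_scored(rng, 50, ties=bool(seed % 2))
    thr = gmean_threshold(s)
    uniq = np.unique(s.scores)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2,
                                 [np.inf]])

    def gmean(t):
        _, _, bacc = _confusion_oracle(s, t)
        pred = s.scores > t
        sens = (pred & (s.labels == 1)).sum() / (s.labels == 1).sum()
        spec = (~pred & (s.labels == 0)).sum() / (s.labels == 0).sum()
        return np.sqrt(sens * spec)

    best = max(gmean(t) for t in candidates)
    assert gmean(thr) == pytest.approx(best, abs=1e-12)
    # ties break toward the smaller threshold
    winners = [t for t in candidates
               if gmean(t) == pytest.approx(best, abs=1e-12)]
    assert thr == min(winners)


def test_monotone_score_transform_preserves_classification():
    rng = np.random.default_rng(0)
    s = _random_scored(rng, 30)
    doubled = _scored(2.0 * s.scores, s.labels)
    pred_a = s.scores > gmean_threshold(s)
    pred_b = doubled.scores > gmean_threshold(doubled)
    assert np.array_equal(pred_a, pred_b)


# -------------------------------------------------------- confusion metrics

def test_textbook_confusion_values():
    s = _scored([0.9, 0.9, 0.1, 0.1], [1, 0, 1, 0])  # TP FP FN TN at 0.5
    f1, acc, bacc = f1_acc_bacc(s, 0.5)
    assert (f1, acc, bacc) == (0.5, 0.5, 0.5)
    perfect = _scored([0.9, 0.1], [1, 0])
    assert f1_acc_bacc(perfect, 0.5) == (1.0, 1.0, 1.0)


@pytest.mark.parametrize("seed", range(5))
def test_confusion_metrics_match_recount_oracle(seed):
    rng = np.random.default_rng(seed)
    s = _random_scored(rng, 100)
    thr = float(rng.random())
    assert f1_acc_bacc(s, thr) == pytest.approx(_confusion_oracle(s, thr),
                                                abs=1e-12)


def test_zero_denominator_f1_reported_as_zero():
    s = _scored([0.1, 0.2, 0.3], [1, 0, 0])
    f1, _, _ = f1_acc_bacc(s, 0.9)        # nothing predicted positive
    assert f1 == 0.0


# ----------------------------------------------------------------- bootstrap

def test_bootstrap_degenerate_distribution_and_determinism():
    assert bootstrap_ci([0.7, 0.7, 0.7], seed=0) == \
        pytest.approx((0.7, 0.7), abs=1e-12)
    a = bootstrap_ci([0.2, 0.5, 0.9], seed=4)
    assert a == bootstrap_ci([0.2, 0.5, 0.9], seed=4)
    lo, hi = a
    assert lo <= np.mean([0.2, 0.5, 0.9]) <= hi
    with pytest.raises(ValueError):
        bootstrap_ci([0.5])


def test_two_subject_bootstrap_matches_exact_enumeration():
    """Values {0,1}: resample means are 0, 0.5, 1 with probs 1/4, 1/2, 1/4,
    so the 2.5/97.5 percentile interval is exactly (0, 1)."""
    assert bootstrap_ci([0.0, 1.0], seed=1) == (0.0, 1.0)


# --------------------------------------------------------------- aggregation

def test_macro_report_is_order_invariant():
    rng = np.random.default_rng(0)
    subjects = []
    for i in range(4):
        s = _random_scored(rng, 40, ties=False)
        subjects.append(evaluate_subject(
            ScoredSet(f"s{i}", s.scores, s.labels)))
    fwd = macro_report(subjects, with_ci=False)
    rev = macro_report(subjects[::-1], with_ci=False)
    for m, entry in fwd["macro"].items():
        assert entry["mean"] == pytest.approx(rev["macro"][m]["mean"],
                                              abs=1e-12)
        assert 0.0 <= entry["mean"] <= 1.0


def test_threshold_fit_on_validation_not_test():
    rng = np.random.default_rng(1)
    val = _random_scored(rng, 40, ties=False)
    test = _random_scored(rng, 40, ties=False)
    r = evaluate_subject(test, validation=val)
    assert r["threshold"] == gmean_threshold(val)
    assert r["threshold_fit_on"] == "validation"
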