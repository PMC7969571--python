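"""Agreement statistics against independent oracles: brute-force pixel
counting for Dice, pairwise concordance for AUC, the closed-form kappa, and
exhaustive confusion-matrix enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axistack.evaluation import (
    ConfusionCounts,
    binary_diagnostics,
    cohen_kappa,
    dice,
    pearson,
    per_class_dice,
    reconstruct_confusion,
    roc,
    wilson_interval,
)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_identical_disjoint_and_formula():
    a = np.zeros((10, 10), bool)
    a[:5] = True
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    # TP=1, FN=1, FP=0 → 2/3
    pred = np.array([[True, False]])
    true = np.array([[True, True]])
    assert dice(pred, true) == pytest.approx(2 / 3)


def test_dice_vacuous_agreement_on_empty_masks():
    empty = np.zeros((4, 4), bool)
    assert dice(empty, empty) == 1.0


def test_dice_shape_mismatch():
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_dice_symmetry_and_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((8, 8)) > 0.6
    b = rng.random((8, 8)) > 0.6
    assert dice(a, b) == dice(b, a)
    perm = rng.permutation(64)
    assert dice(a.ravel()[perm], b.ravel()[perm]) == pytest.approx(dice(a, b))


def test_per_class_dice_matches_brute_force_counts():
    """Corrupted label maps: per-class Dice equals 2TP/(2TP+FP+FN) counted
    independently pixel by pixel."""
    rng = np.random.default_rng(3)
    true = rng.integers(0, 9, size=(50, 60)).astype(np.uint8)
    pred = true.copy()
    flip = rng.random(true.shape) < 0.1
    pred[flip] = rng.integers(0, 9, size=int(flip.sum()))
    scores = per_class_dice(pred, true)
    for c, score in scores.items():
        tp = fp = fn = 0
        for p, t in zip(pred.ravel(), true.ravel()):
            if p == c and t == c:
                tp += 1
            elif p == c:
                fp += 1
            elif t == c:
                fn += 1
        assert score == pytest.approx(2 * tp / (2 * tp + fp + fn))


def test_per_class_dice_total_confusion():
    true = np.full((6, 6), 3, dtype=np.uint8)
    pred = np.full((6, 6), 4, dtype=np.uint8)
    scores = per_class_dice(pred, true)
    assert scores[3] == 0.0 and scores[4] == 0.0


def test_per_class_dice_perfect():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
    scores = per_class_dice(labels, labels)
    assert all(v == 1.0 for v in scores.values())
    assert np.mean(list(scores.values())) == 1.0


# ---------------------------------------------------------------------------
# binary diagnostics and kappa
# ---------------------------------------------------------------------------

def test_perfect_agreement_diagnostics():
    d = binary_diagnostics(ConfusionCounts(TP=1, FP=0, FN=0, TN=1))
    assert (d.accuracy, d.sensitivity, d.specificity, d.kappa) == (1.0, 1.0, 1.0, 1.0)


def test_kappa_printed_worked_examples():
    """Confusion matrices reconstructed from printed accuracy/sensitivity/
    specificity reproduce the reported kappa values."""
    d = binary_diagnostics(ConfusionCounts(TP=43, FP=11, FN=8, TN=138))
    assert round(d.kappa, 2) == 0.75
    d = binary_diagnostics(ConfusionCounts(TP=7, FP=3, FN=0, TN=44))
    assert round(d.kappa, 2) == 0.79
    assert d.sensitivity == 1.0


def test_undefined_statistics_absent():
    d = binary_diagnostics(ConfusionCounts(TP=5, FP=2, FN=3, TN=0))
    assert d.specificity is not None
    d = binary_diagnostics(ConfusionCounts(TP=5, FP=0, FN=3, TN=0))
    assert d.specificity is None
    d = binary_diagnostics(ConfusionCounts(TP=0, FP=2, FN=0, TN=5))
    assert d.sensitivity is None
    # all one class: chance agreement is 1, kappa undefined
    assert binary_diagnostics(ConfusionCounts(TP=9, FP=0, FN=0, TN=0)).kappa is None


def test_kappa_one_iff_no_errors_and_zero_under_independence():
    rng = np.random.default_rng(5)
    for _ in range(200):
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, 20, size=4))
        counts = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
        if counts.n == 0:
            continue
        k = cohen_kappa(counts)
        if k is None:
            continue
        both_classes = (tp + fn) > 0 and (tn + fp) > 0
        if fp == 0 and fn == 0 and both_classes:
            assert k == pytest.approx(1.0)
        elif k == 1.0:
            assert fp == 0 and fn == 0
    # rows and columns independent → kappa 0
    assert cohen_kappa(ConfusionCounts(TP=5, FP=5, FN=5, TN=5)) == pytest.approx(0.0)


def test_kappa_matches_sklearn():
    """Independent cross-check against sklearn's cohen_kappa_score."""
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(6)
    for _ in range(20):
        tp, fp, fn, tn = (int(v) for v in rng.integers(1, 30, size=4))
        truth = [1] * (tp + fn) + [0] * (fp + tn)
        pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        ours = cohen_kappa(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
        assert ours == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)


# ---------------------------------------------------------------------------
# confusion-matrix reconstruction
# ---------------------------------------------------------------------------

def test_reconstruct_trivial_perfect_pair():
    sols = reconstruct_confusion(2, 100, 100, 100)
    assert sols == [ConfusionCounts(TP=1, FN=0, FP=0, TN=1)]


def test_reconstruct_unique_solutions_from_printed_stats():
    sols = reconstruct_confusion(200, 84.3, 92.6, 90.5)
    assert sols == [ConfusionCounts(TP=43, FN=8, FP=11, TN=138)]
    sols = reconstruct_confusion(54, 100, 93.6, 94.4)
    assert sols == [ConfusionCounts(TP=7, FN=0, FP=3, TN=44)]


def test_reconstruct_no_solution_is_empty():
    assert reconstruct_confusion(3, 100, 100, 50) == []


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_reconstruct_inverts_printed_diagnostics(seed):
    """reconstruct ∘ diagnostics is the identity on the printed-precision
    equivalence class: the true matrix is always among the solutions."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 300))
    pos = int(rng.integers(1, n))
    tp = int(rng.integers(0, pos + 1))
    tn = int(rng.integers(0, n - pos + 1))
    counts = ConfusionCounts(TP=tp, FN=pos - tp, FP=n - pos - tn, TN=tn)
    d = binary_diagnostics(counts)
    # half-up at 1 decimal, the convention printed figures follow
    printed = lambda v: float(np.floor(v * 1000 + 0.5) / 10)  # noqa: E731
    sols = reconstruct_confusion(n, printed(d.sensitivity), printed(d.specificity),
                                 printed(d.accuracy))
    assert counts in sols


# ---------------------------------------------------------------------------
# Wilson intervals, Pearson, ROC
# ---------------------------------------------------------------------------

def test_wilson_reproduces_printed_intervals():
    lo, hi = wilson_interval(9, 10, 0.95)
    assert round(lo, 3) == 0.596 and round(hi, 3) == 0.982
    lo, hi = wilson_interval(10, 10, 0.95)
    assert hi == 1.0
    assert 0.722 <= lo <= 0.723


def test_wilson_bounds_contain_the_estimate():
    rng = np.random.default_rng(8)
    for _ in range(50):
        trials = int(rng.integers(1, 60))
        successes = int(rng.integers(0, trials + 1))
        lo, hi = wilson_interval(successes, trials, 0.95)
        assert 0.0 <= lo <= successes / trials <= hi <= 1.0


def test_pearson_exact_lines_and_three_points():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r, r2 = pearson(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, r2 = pearson(x, -x)
    assert (r, r2) == (pytest.approx(-1.0), pytest.approx(1.0))
    _, r2 = pearson([1, 2, 3], [1, 2, 4])
    assert round(r2, 4) == 0.9643


def test_pearson_rejects_zero_variance():
    with pytest.raises(ValueError):
        pearson([1, 1, 1], [1, 2, 3])


def test_roc_separable_and_uninformative():
    r = roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert r.auc == 1.0
    r = roc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
    assert r.auc == 0.5


def test_roc_small_worked_example():
    """3 of 4 positive–negative pairs concordant → AUC 0.75."""
    r = roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert r.auc == pytest.approx(0.75)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc([0.1, 0.2], [1, 1])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_auc_equals_pairwise_concordance(seed):
    """AUC equals the Mann–Whitney statistic, checked exhaustively on all
    positive–negative pairs of small instances."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    scores = np.round(rng.random(n), 2)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    r = roc(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    assert r.auc == pytest.approx((wins + 0.5 * ties) / (len(pos) * len(neg)))


def test_youden_cutoff_tie_breaks_to_lower_threshold():
    # two cut-offs reach J = 0.5; the lower one must be chosen
    scores = [0.1, 0.3, 0.6, 0.9]
    labels = [0, 1, 0, 1]
    r = roc(scores, labels)
    assert r.youden_threshold == pytest.approx(0.3)
    assert r.diagnostics_at_cutoff.accuracy == pytest.approx(0.75)
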