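"""Training loop behaviour and the eight evaluation metrics."""

import numpy as np
import pytest
from scipy import stats

from abagnet.io_formats import ALPHABET, InteractionPair, SequenceRecord
from abagnet.model import Featurizer, ModelConfig, build_model
from abagnet.train_eval import (
    PairDataset,
    TrainConfig,
    compare_runs,
    confusion_counts,
    evaluate,
    metrics_report,
    pr_auc,
    roc_auc,
    threshold_metrics,
    train,
)

RNG = np.random.default_rng(61)


# ---------------------------------------------------------------------------
# confusion counts

def test_confusion_counts_examples():
    assert confusion_counts(np.array([0.9, 0.2]), np.array([1, 0])) == (1, 0, 1, 0)
    scores = np.array([1.0, 0.0, 1.0, 0.0])
    labels = np.array([1, 0, 1, 0])
    TP, FP, TN, FN = confusion_counts(scores, labels)
    assert FP == FN == 0 and TP == 2 and TN == 2


def test_confusion_counts_match_loop_oracle():
    scores = RNG.random(50)
    labels = (RNG.random(50) < 0.4).astype(int)
    TP, FP, TN, FN = confusion_counts(scores, labels, 0.5)
    tp = fp = tn = fn = 0
    for s, l in zip(scores, labels):
        pred = 1 if s >= 0.5 else 0
        if pred and l:
            tp += 1
        elif pred and not l:
            fp += 1
        elif not pred and not l:
            tn += 1
        else:
            fn += 1
    assert (TP, FP, TN, FN) == (tp, fp, tn, fn)
    assert TP + FP + TN + FN == 50


def test_confusion_counts_validation():
    with pytest.raises(ValueError, match="length"):
        confusion_counts(np.zeros(3), np.zeros(4))
    with pytest.raises(ValueError, match="threshold"):
        confusion_counts(np.zeros(3), np.zeros(3), threshold=1.0)


# ---------------------------------------------------------------------------
# threshold metrics

def test_threshold_metrics_hand_computed_case():
    acc, pre, rec, spe, f1, mcc = threshold_metrics(3, 1, 4, 2)
    assert acc == pytest.approx(0.7)
    assert pre == pytest.approx(0.75)
    assert rec == pytest.approx(0.6)
    assert spe == pytest.approx(0.8)
    assert f1 == pytest.approx(6 / 9)
    assert mcc == pytest.approx(10 / np.sqrt(600))


def test_threshold_metrics_perfect_prediction():
    assert threshold_metrics(5, 0, 7, 0) == (1, 1, 1, 1, 1, 1)


def test_threshold_metrics_degenerate_all_negative():
    acc, pre, rec, spe, f1, mcc = threshold_metrics(0, 0, 9, 0)
    assert acc == 1.0 and spe == 1.0
    assert pre == rec == f1 == mcc == 0.0  # zero-denominator convention


def test_threshold_metrics_bounds_random_counts():
    for _ in range(30):
        TP, FP, TN, FN = RNG.integers(0, 20, size=4)
        if TP + FP + TN + FN == 0:
            continue
        acc, pre, rec, spe, f1, mcc = threshold_metrics(TP, FP, TN, FN)
        assert all(0 <= m <= 1 for m in (acc, pre, rec, spe, f1))
        assert -1 <= mcc <= 1
        assert acc == pytest.approx((TP + TN) / (TP + FP + TN + FN))


def test_threshold_metrics_rejects_negative_counts():
    with pytest.raises(ValueError):
        threshold_metrics(-1, 0, 1, 0)


# ---------------------------------------------------------------------------
# AUC / AUPR

def test_auc_perfect_and_tied():
    labels = np.array([0, 0, 1, 1])
    assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0
    assert pr_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0
    assert roc_auc(np.full(4, 0.5), labels) == 0.5


def test_auc_matches_pair_counting_oracle():
    for _ in range(30):
        scores = RNG.random(30)
        labels = (RNG.random(30) < 0.5).astype(int)
        if labels.min() == labels.max():
            continue
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(expected)


def test_auc_invariant_under_monotone_transform():
    scores = RNG.random(40)
    labels = (RNG.random(40) < 0.5).astype(int)
    a = roc_auc(scores, labels)
    b = roc_auc(np.exp(5 * scores) + 3, labels)
    assert a == pytest.approx(b)


def test_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc(np.array([0.2, 0.8]), np.array([1, 1]))
    with pytest.raises(ValueError):
        pr_auc(np.array([0.2, 0.8]), np.array([0, 0]))


def test_metrics_report_consistency():
    scores = RNG.random(40)
    labels = (RNG.random(40) < 0.5).astype(int)
    rep = metrics_report(scores, labels)
    assert rep.TP + rep.FP + rep.TN + rep.FN == 40
    assert rep["ACC"] == rep.ACC
    assert set(rep.to_dict()) == {"TP", "FP", "TN", "FN", "ACC", "Pre",
                                  "Recall", "Spe", "F1", "MCC", "AUC", "AUPR"}


# ---------------------------------------------------------------------------
# multi-run comparison

def test_compare_runs_identical_groups():
    assert compare_runs([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]) == 1.0


def test_compare_runs_extreme_separation():
    assert compare_runs([0, 0, 0, 0], [1, 1, 1, 1]) < 1e-4


def test_compare_runs_matches_closed_form_welch():
    a = np.array([0.71, 0.74, 0.69, 0.73, 0.70])
    b = np.array([0.65, 0.66, 0.68, 0.64, 0.67])
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t = (a.mean() - b.mean()) / np.sqrt(va / 5 + vb / 5)
    df = (va / 5 + vb / 5) ** 2 / (
        (va / 5) ** 2 / 4 + (vb / 5) ** 2 / 4
    )
    expected = 2 * stats.t.sf(abs(t), df)
    assert compare_runs(a, b) == pytest.approx(expected, rel=1e-10)


def test_compare_runs_needs_two_samples():
    with pytest.raises(ValueError):
        compare_runs([1.0], [0.5, 0.6])


# ---------------------------------------------------------------------------
# training loop

def _separable_dataset(n=40):
    """Positives share a strong antibody motif: linearly separable."""
    rng = np.random.default_rng(97)  # fixed: datasets identical across calls
    seqs, pairs = {}, []
    motif = "WWWWWW"
    for i in range(n):
        label = i % 2
        ab = "".join(rng.choice(list(ALPHABET), size=24))
        if label:
            ab = motif + ab[6:]
        ag = "".join(rng.choice(list(ALPHABET), size=24))
        ab_r, ag_r = SequenceRecord(f"ab{i}", ab), SequenceRecord(f"ag{i}", ag)
        seqs[ab_r.id], seqs[ag_r.id] = ab_r, ag_r
        pairs.append(InteractionPair(ab_r.id, ag_r.id, label))
    return pairs, seqs


def _tiny_setup(seed=0):
    model = build_model(ModelConfig.tiny(), seed=seed)
    pairs, seqs = _separable_dataset()
    ds = PairDataset(pairs, seqs, Featurizer(model.cfg.k))
    return model, ds


def test_training_reduces_loss_on_separable_data():
    model, ds = _tiny_setup()
    cfg = TrainConfig(epochs=6, learning_rate=2e-3, batch_size=16, seed=0)
    _, history = train(model, ds, None, cfg)
    assert history[-1]["train_loss"] < history[0]["train_loss"]
    report = evaluate(model, ds)
    assert report.ACC > 0.5


def test_training_zero_epochs_leaves_model_unchanged():
    model, ds = _tiny_setup()
    before = [p.data.copy() for p in model.parameters()]
    _, history = train(model, ds, None, TrainConfig(epochs=0, seed=0))
    assert history == []
    for p, b in zip(model.parameters(), before):
        np.testing.assert_array_equal(p.data, b)


def test_training_deterministic_given_seed():
    h1 = train(*_tiny_setup(seed=4)[:1],
               _tiny_setup(seed=4)[1], None,
               TrainConfig(epochs=2, learning_rate=1e-3, batch_size=16,
                           seed=9))[1]
    h2 = train(*_tiny_setup(seed=4)[:1],
               _tiny_setup(seed=4)[1], None,
               TrainConfig(epochs=2, learning_rate=1e-3, batch_size=16,
                           seed=9))[1]
    assert h1 == h2


def test_training_rejects_empty_dataset():
    model, ds = _tiny_setup()
    empty = PairDataset([], ds.sequences, ds.featurizer)
    with pytest.raises(ValueError, match="empty"):
        train(model, empty, None, TrainConfig(epochs=1))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
    assert TrainConfig().epochs == 80
    assert TrainConfig().learning_rate == 5e-4
    assert TrainConfig().batch_size == 128
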