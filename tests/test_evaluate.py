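"""Metrics (CA, MCC, per-gesture recall), Friedman test, and the two
train/test scenarios."""

import numpy as np
import pytest
from scipy.stats import friedmanchisquare

import oracles
from emgsrd import (
    SRDGroup,
    between_srd_eval,
    classification_accuracy,
    friedman_test,
    mcc_macro,
    mcc_per_class,
    per_gesture_accuracy,
    pooled_confusion,
    within_srd_eval,
)
from emgsrd.decode import ClassifierSpec, default_spec
from emgsrd.evaluate import ConfusionMatrix, confusion_from_predictions


def _cm(counts, labels=None):
    counts = np.asarray(counts)
    labels = labels or tuple(f"c{i}" for i in range(counts.shape[0]))
    return ConfusionMatrix(counts=counts, labels=labels)


def test_accuracy_hand_values():
    assert classification_accuracy(_cm([[5, 0], [0, 5]])) == 100.0
    assert classification_accuracy(_cm([[3, 1], [1, 3]])) == 75.0
    with pytest.raises(ValueError):
        classification_accuracy(_cm([[0, 0], [0, 0]]))


def test_accuracy_matches_loop_oracle(rng):
    for _ in range(20):
        counts = rng.integers(0, 40, size=(5, 5))
        counts[0, 0] += 1  # non-empty
        cm = _cm(counts)
        assert classification_accuracy(cm) == pytest.approx(
            oracles.accuracy_oracle(counts.tolist())
        )


def test_mcc_hand_values():
    assert mcc_per_class(_cm([[4, 0], [0, 4]]), 0) == pytest.approx(1.0)
    assert mcc_per_class(_cm([[0, 4], [4, 0]]), 0) == pytest.approx(-1.0)
    for j in (0, 1):
        assert mcc_per_class(_cm([[3, 1], [1, 3]]), j) == pytest.approx(0.5)
    assert mcc_macro(_cm([[3, 1], [1, 3]])) == pytest.approx(0.5)


def test_mcc_zero_denominator_convention():
    # classifier that always predicts class 0: TN = 0 for class 0
    assert mcc_per_class(_cm([[4, 0], [4, 0]]), 0) == 0.0
    assert mcc_per_class(_cm([[4, 0], [4, 0]]), 1) == 0.0


def test_mcc_macro_is_one_iff_diagonal(rng):
    diag = np.diag(rng.integers(1, 30, size=6))
    assert mcc_macro(_cm(diag)) == pytest.approx(1.0)
    off = diag.copy()
    off[0, 1] = 3
    assert mcc_macro(_cm(off)) < 1.0


def test_mcc_matches_loop_oracle_and_stays_bounded(rng):
    for _ in range(20):
        counts = rng.integers(0, 30, size=(4, 4))
        counts[1, 1] += 1
        cm = _cm(counts)
        for j in range(4):
            v = mcc_per_class(cm, j)
            assert v == pytest.approx(oracles.mcc_oracle(counts.tolist(), j), rel=1e-12)
            assert -1.0 <= v <= 1.0


def test_per_gesture_accuracy():
    assert np.allclose(per_gesture_accuracy(_cm([[5, 0], [0, 2]])), [100.0, 100.0])
    cm = _cm([[0, 5], [0, 7]])
    assert np.allclose(per_gesture_accuracy(cm), [0.0, 100.0])
    counts = np.random.default_rng(0).integers(0, 20, size=(6, 6))
    counts += np.eye(6, dtype=int)
    assert np.allclose(
        per_gesture_accuracy(_cm(counts)), oracles.per_class_recall_oracle(counts.tolist())
    )


def test_friedman_all_ties():
    stat, p = friedman_test(np.ones((4, 3)))
    assert stat == 0.0 and p == 1.0


def test_friedman_dominant_column():
    """Strict identical ordering in every block forces the 3x3 statistic to 6."""
    scores = np.array([[3.0, 1.0, 2.0], [5.0, 2.0, 4.0], [9.0, 1.0, 5.0]])
    stat, p = friedman_test(scores)
    assert stat == pytest.approx(6.0)
    assert p == pytest.approx(np.exp(-3.0), rel=1e-9)  # chi2.sf(6, 2)


def test_friedman_matches_reference(rng):
    for _ in range(25):
        n = int(rng.integers(3, 10))
        k = int(rng.integers(3, 6))
        table = rng.normal(size=(n, k))
        stat, p = friedman_test(table)
        ref_stat, ref_p = friedmanchisquare(*table.T)
        assert stat == pytest.approx(ref_stat, abs=1e-8)
        assert p == pytest.approx(ref_p, abs=1e-8)


def test_friedman_degenerate_shapes_rejected():
    with pytest.raises(ValueError):
        friedman_test(np.ones((1, 3)))
    with pytest.raises(ValueError):
        friedman_test(np.ones((3, 1)))


def test_confusion_from_predictions_counts():
    cm = confusion_from_predictions(
        ["T", "T", "I", "I"], ["T", "I", "I", "I"], ("T", "I")
    )
    assert np.array_equal(cm.counts, [[1, 1], [0, 2]])
    assert cm.total == 4


def test_confusion_matrix_csv_roundtrip(tmp_path, rng):
    counts = rng.integers(0, 20, size=(3, 3))
    cm = _cm(counts, labels=("T", "I", "HC"))
    path = tmp_path / "cm.csv"
    cm.to_csv(path)
    back = ConfusionMatrix.from_csv(path)
    assert np.array_equal(back.counts, cm.counts)
    assert back.labels == cm.labels


def test_within_eval_deterministic(tiny_dataset):
    srd = SRDGroup(2.0)
    a = within_srd_eval(tiny_dataset, srd, "RMS", default_spec("LDA"))
    b = within_srd_eval(tiny_dataset, srd, "RMS", default_spec("LDA"))
    assert len(a) == 1  # one subject
    assert a[0].ca == b[0].ca
    assert a[0].mcc_macro == b[0].mcc_macro
    assert np.array_equal(a[0].confusion.counts, b[0].confusion.counts)
    assert 0.0 <= a[0].ca <= 100.0


def test_within_eval_missing_trial_rejected(tiny_dataset):
    no_trial3 = [r for r in tiny_dataset if r.trial_index != 3]
    with pytest.raises(ValueError):
        within_srd_eval(no_trial3, SRDGroup(1.0), "RMS", default_spec("LDA"))


def test_between_eval_pooled_ca_is_weighted_mean(tiny_dataset):
    results = between_srd_eval(
        tiny_dataset,
        SRDGroup(1.0),
        "RMS",
        default_spec("LDA"),
        srd_tests=[SRDGroup(1.0), SRDGroup(2.0)],
    )
    assert len(results) == 2
    weights = np.array([r.n_test for r in results], float)
    cas = np.array([r.ca for r in results])
    pooled = pooled_confusion(results)
    assert classification_accuracy(pooled) == pytest.approx(
        np.sum(weights * cas) / np.sum(weights)
    )


def test_between_faithful_includes_train_windows(tiny_dataset):
    """Faithful mode with 1-NN memorizes the diagonal cell perfectly."""
    knn1 = ClassifierSpec(kind="KNN", hyperparams={"n_neighbors": 1})
    res = between_srd_eval(
        tiny_dataset, SRDGroup(1.0), "NTDF", knn1, srd_tests=[SRDGroup(1.0)]
    )
    assert res[0].ca == 100.0
    strict = between_srd_eval(
        tiny_dataset, SRDGroup(1.0), "NTDF", knn1, srd_tests=[SRDGroup(1.0)], strict=True
    )
    assert strict[0].ca < 100.0
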