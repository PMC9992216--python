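"""Evaluation scenarios and metrics for SRD gesture-decoding experiments.

Implements the two train/test scenarios used to study signal-recording
duration (SRD):

* **Within-SRD** — per subject, train on trials 1+2 of one SRD group and
  test on trial 3 of the same group (the conventional protocol).
* **Between-SRD** — per subject, train on one SRD group and test against
  every SRD group. In faithful mode both sides use all trials, so training
  windows can legitimately reappear in the test set when the test prefix
  overlaps the training prefix; strict mode instead holds out trial 3.

Metrics: classification accuracy (CA, percent), one-vs-rest Matthews
correlation per class and its macro average, per-gesture recall, and the
Friedman rank test for comparing SRD groups across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .decode import ClassifierSpec, predict, train
from .features import FeatureMatrix, FeatureParams, build_feature_matrix
from .preprocess import SRD_LENGTHS_S, SRDGroup, SegmentationParams
from .simulate import CLASS_CODES, Recording


@dataclass
class ConfusionMatrix:
    """Squared class-count table; rows = true class, columns = predicted."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        """Write as labeled CSV: rows true classes, columns predicted."""
        import pandas as pd

        pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, index_label="true\\pred"
        )

    @staticmethod
    def from_csv(path) -> "ConfusionMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return ConfusionMatrix(
            counts=df.to_numpy(dtype=np.int64), labels=tuple(df.columns)
        )


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    labels = tuple(labels)
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred, strict=True):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def classification_accuracy(cm: ConfusionMatrix) -> float:
    """CA in percent: 100 * trace / total test windows."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def mcc_per_class(cm: ConfusionMatrix, j: int) -> float:
    """One-vs-rest Matthews correlation of class j; 0 when undefined."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    tp = c[j, j]
    fn = c[j, :].sum() - tp
    fp = c[:, j].sum() - tp
    tn = c.sum() - tp - fn - fp
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float(((tp * tn) - (fp * fn)) / denom)


def mcc_macro(cm: ConfusionMatrix) -> float:
    """Macro-averaged MCC: unweighted mean of the per-class values."""
    k = len(cm.labels)
    return float(np.mean([mcc_per_class(cm, j) for j in range(k)]))


def per_gesture_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall in percent (row-normalized diagonal); 0 for empty rows."""
    row = cm.counts.sum(axis=1).astype(float)
    diag = np.diag(cm.counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(row > 0, 100.0 * diag / row, 0.0)
    return acc


def friedman_test(scores: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over a blocks x treatments score table.

    Ranks within each block (average ranks on ties), standard tie-corrected
    chi-square statistic, p from the chi-square distribution with
    (treatments - 1) degrees of freedom. Fully tied tables give (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    n, k = scores.shape
    ranks = np.apply_along_axis(sstats.rankdata, 1, scores)
    ssbn = float(np.sum(ranks.sum(axis=0) ** 2))
    ties = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * (k**3 - k))
    numer = 12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)
    if c == 0.0:
        return 0.0, 1.0
    stat = numer / c
    p = float(sstats.chi2.sf(stat, k - 1))
    return float(stat), p


@dataclass
class ExperimentResult:
    """Scores of one evaluation cell."""

    scenario: str  # "within" | "between"
    srd_train_s: float
    srd_test_s: float
    feature_set: str
    classifier: str
    subject_id: int
    ca: float  # percent
    mcc_macro: float
    confusion: ConfusionMatrix

    def __post_init__(self) -> None:
        if not (0.0 <= self.ca <= 100.0):
            raise ValueError("ca must lie in [0, 100]")
        if not (-1.0 <= self.mcc_macro <= 1.0):
            raise ValueError("mcc_macro must lie in [-1, 1]")

    @property
    def n_test(self) -> int:
        return self.confusion.total


def _label_order(recordings: Sequence[Recording]) -> tuple[str, ...]:
    present = {r.class_code for r in recordings}
    return tuple(c for c in CLASS_CODES if c in present)


def _by_subject(recordings: Sequence[Recording]) -> dict[int, list[Recording]]:
    groups: dict[int, list[Recording]] = {}
    for r in recordings:
        groups.setdefault(r.subject_id, []).append(r)
    return dict(sorted(groups.items()))


def _select_trials(recs: Sequence[Recording], trials: Sequence[int]) -> list[Recording]:
    out = [r for r in recs if r.trial_index in trials]
    have = {r.trial_index for r in out}
    missing = set(trials) - have
    if missing:
        raise ValueError(f"missing trials {sorted(missing)}")
    return out


def _score(
    fm_train: FeatureMatrix,
    fm_test: FeatureMatrix,
    spec: ClassifierSpec,
    labels: tuple[str, ...],
) -> tuple[float, float, ConfusionMatrix]:
    model = train(fm_train, spec)
    y_pred = predict(model, fm_test)
    cm = confusion_from_predictions(fm_test.labels, y_pred, labels)
    return classification_accuracy(cm), mcc_macro(cm), cm


def within_srd_eval(
    dataset: Sequence[Recording],
    srd: SRDGroup,
    feature_set: str,
    spec: ClassifierSpec,
    seg_params: SegmentationParams = SegmentationParams(),
    feature_params: FeatureParams | None = None,
    train_trials: tuple[int, ...] = (1, 2),
    test_trial: int = 3,
) -> list[ExperimentResult]:
    """Within-SRD scenario: per subject, trials 1+2 train, trial 3 test."""
    labels = _label_order(dataset)
    results = []
    for subject, recs in _by_subject(dataset).items():
        fm_train = build_feature_matrix(
            _select_trials(recs, train_trials), srd, seg_params, feature_set, feature_params
        )
        fm_test = build_feature_matrix(
            _select_trials(recs, (test_trial,)), srd, seg_params, feature_set, feature_params
        )
        ca, mcc, cm = _score(fm_train, fm_test, spec, labels)
        results.append(
            ExperimentResult(
                scenario="within",
                srd_train_s=srd.length_s,
                srd_test_s=srd.length_s,
                feature_set=feature_set,
                classifier=spec.kind,
                subject_id=subject,
                ca=ca,
                mcc_macro=mcc,
                confusion=cm,
            )
        )
    return results


def between_srd_eval(
    dataset: Sequence[Recording],
    srd_train: SRDGroup,
    feature_set: str,
    spec: ClassifierSpec,
    seg_params: SegmentationParams = SegmentationParams(),
    feature_params: FeatureParams | None = None,
    srd_tests: Sequence[SRDGroup] | None = None,
    strict: bool = False,
) -> list[ExperimentResult]:
    """Between-SRD scenario: train one SRD group, test against every group.

    Faithful mode (default) trains and tests on all trials, as the protocol
    states; strict mode trains on trials 1+2 and tests on trial 3 only.
    """
    if srd_tests is None:
        srd_tests = [SRDGroup(s) for s in SRD_LENGTHS_S]
    labels = _label_order(dataset)
    results = []
    for subject, recs in _by_subject(dataset).items():
        train_recs = _select_trials(recs, (1, 2)) if strict else recs
        test_recs = _select_trials(recs, (3,)) if strict else recs
        fm_train = build_feature_matrix(
            train_recs, srd_train, seg_params, feature_set, feature_params
        )
        model = train(fm_train, spec)
        for srd_test in srd_tests:
            fm_test = build_feature_matrix(
                test_recs, srd_test, seg_params, feature_set, feature_params
            )
            y_pred = predict(model, fm_test)
            cm = confusion_from_predictions(fm_test.labels, y_pred, labels)
            results.append(
                ExperimentResult(
                    scenario="between",
                    srd_train_s=srd_train.length_s,
                    srd_test_s=srd_test.length_s,
                    feature_set=feature_set,
                    classifier=spec.kind,
                    subject_id=subject,
                    ca=classification_accuracy(cm),
                    mcc_macro=mcc_macro(cm),
                    confusion=cm,
                )
            )
    return results


def pooled_confusion(results: Sequence[ExperimentResult]) -> ConfusionMatrix:
    """Sum of the confusion matrices of several results (same label order)."""
    if not results:
        raise ValueError("no results to pool")
    labels = results[0].confusion.labels
    if any(r.confusion.labels != labels for r in results):
        raise ValueError("label order mismatch")
    counts = np.sum([r.confusion.counts for r in results], axis=0)
    return ConfusionMatrix(counts=counts, labels=labels)
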