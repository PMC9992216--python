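"""Gesture decoders: LDA, KNN and random-forest classifiers over feature matrices.

Thin, deterministic wrappers around scikit-learn estimators. Feature scaling
(z-score) is fit on training rows only; KNN and LDA default to scaled inputs
since the feature sets mix magnitudes (e.g. SIS vs mMSR), while trees are
scale-invariant and default to raw features.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("LDA", "KNN", "RF")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind, hyperparameters and scaling policy.

    Hyperparameters: KNN ``n_neighbors`` (default 5, Euclidean metric);
    RF ``n_trees`` (default 100) and ``seed``; LDA has none (automatic
    shrinkage fallback on singular scatter).
    """

    kind: str
    hyperparams: dict = field(default_factory=dict)
    scaling: str = "default"  # "default" | "zscore" | "none"

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if self.scaling not in ("default", "zscore", "none"):
            raise ValueError("scaling must be 'default', 'zscore' or 'none'")
        if self.kind == "KNN" and self.hyperparams.get("n_neighbors", 5) < 1:
            raise ValueError("KNN requires n_neighbors >= 1")
        if self.kind == "RF" and self.hyperparams.get("n_trees", 100) < 1:
            raise ValueError("RF requires n_trees >= 1")

    @property
    def effective_scaling(self) -> str:
        if self.scaling != "default":
            return self.scaling
        return "none" if self.kind == "RF" else "zscore"


def default_spec(kind: str, seed: int = 0) -> ClassifierSpec:
    if kind == "RF":
        return ClassifierSpec(kind="RF", hyperparams={"n_trees": 100, "seed": seed})
    if kind == "KNN":
        return ClassifierSpec(kind="KNN", hyperparams={"n_neighbors": 5})
    return ClassifierSpec(kind="LDA")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    scaler: StandardScaler | None
    clf: object
    classes_: np.ndarray
    n_features: int


def _make_estimator(spec: ClassifierSpec):
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis(solver="svd")
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.hyperparams.get("n_neighbors", 5))
    return RandomForestClassifier(
        n_estimators=spec.hyperparams.get("n_trees", 100),
        random_state=spec.hyperparams.get("seed", 0),
        n_jobs=1,
    )


def train(features: FeatureMatrix, spec: ClassifierSpec) -> TrainedModel:
    """Fit a classifier; the scaler (if any) sees training rows only."""
    x, y = features.values, features.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    scaler = None
    if spec.effective_scaling == "zscore":
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
    clf = _make_estimator(spec)
    try:
        clf.fit(x, y)
    except np.linalg.LinAlgError:
        if spec.kind != "LDA":
            raise
        logger.warning("LDA scatter singular; falling back to shrinkage LDA")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(x, y)
    return TrainedModel(
        spec=spec, scaler=scaler, clf=clf, classes_=classes, n_features=x.shape[1]
    )


def predict(model: TrainedModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """One predicted class code per row."""
    x = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(features)
    if x.shape[0] == 0:
        return np.array([], dtype=model.classes_.dtype)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features}, got {x.shape[1]}"
        )
    if model.scaler is not None:
        x = model.scaler.transform(x)
    return model.clf.predict(x)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize model (with its spec echo) to a single file."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise ValueError("file does not contain a TrainedModel")
    return model
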