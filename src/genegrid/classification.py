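"""Uniform train/predict contract over the two supported classifiers.

SVM: RBF kernel, C = 1, kernel width 1/n_features, with per-feature
standardization learned on the training data (stored in the model, never
refitted on test data).  Random forest: 500 trees, sqrt(p) candidate
features per split.  Neither is tuned; both are fully determined by the
seed and the training bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .transforms import FeatureBlock

__all__ = ["ClassifierSpec", "TrainedModel", "make_classifier", "train", "predict"]

CLASSIFIER_KINDS = ("svm", "random_forest")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind + the few hyperparameters this workbench exposes."""

    kind: str  # "svm" | "random_forest"
    seed: int = 0
    svm_c: float = 1.0
    svm_gamma: float | str = "auto"  # "auto" = 1 / n_features
    n_trees: int = 500
    max_features: str | float = "sqrt"

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"classifier kind must be one of {CLASSIFIER_KINDS}")


def make_classifier(spec: ClassifierSpec):
    """Fresh unfitted sklearn estimator for a spec."""
    if spec.kind == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="rbf", C=spec.svm_c, gamma=spec.svm_gamma)),
            ]
        )
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.max_features,
        random_state=spec.seed,
    )


@dataclass
class TrainedModel:
    """Fitted predictor plus the contract needed to apply it safely."""

    estimator: object
    feature_names: tuple[str, ...]
    classes: tuple

    def __post_init__(self):
        self.feature_names = tuple(self.feature_names)
        self.classes = tuple(self.classes)


def train(spec: ClassifierSpec, block: FeatureBlock, labels) -> TrainedModel:
    """Fit a classifier on a feature block (features x samples)."""
    y = np.asarray(labels)
    if block.n_samples != y.size:
        raise ValueError(f"{block.n_samples} samples but {y.size} labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    est = make_classifier(spec)
    est.fit(block.matrix.T, y)
    return TrainedModel(est, block.names, tuple(classes))


def predict(model: TrainedModel, block: FeatureBlock) -> np.ndarray:
    """Predict one label per sample of the block.

    The block's feature names must match the training block exactly.
    """
    if tuple(block.names) != model.feature_names:
        raise ValueError(
            f"feature mismatch: model trained on {list(model.feature_names)}, "
            f"got {list(block.names)}"
        )
    if block.n_samples == 0:
        return np.asarray([], dtype=object)
    return np.asarray(model.estimator.predict(block.matrix.T))
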