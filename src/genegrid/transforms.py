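"""Classifier-side feature construction.

Two optional transforms sit between gene selection and classifier training:

* MDL discretization of each feature into ordinal interval indices
  (:class:`MDLDiscretizer`), with cuts learned on training samples only;
* feature-vector addition (:class:`FeatureVectorAddition`): the expression
  vectors of the k selected same-direction genes are summed into a single
  composite feature, which can amplify a shared class pattern and average
  out outlying values of individual genes.

When both are enabled the composite is formed first from raw values and the
cuts are then learned on the composite; discretizing before summation would
destroy the amplification the composite is meant to provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .mdl import assign_intervals, mdl_discretize

__all__ = [
    "FeatureBlock",
    "MDLDiscretizer",
    "FeatureVectorAddition",
    "fit_discretizer",
    "apply_discretizer",
    "feature_vector_addition",
]


@dataclass
class FeatureBlock:
    """A features x samples block with provenance for the functional API."""

    matrix: np.ndarray  # features x samples
    names: tuple[str, ...]
    encoding: str = "numeric"  # "numeric" | "interval-index"
    pattern: str | None = None  # total | up | down (selection provenance)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.names = tuple(self.names)
        if self.matrix.shape[0] != len(self.names):
            raise ValueError(
                f"{len(self.names)} names for {self.matrix.shape[0]} feature rows"
            )
        if self.encoding not in ("numeric", "interval-index"):
            raise ValueError(f"unknown encoding {self.encoding!r}")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


class MDLDiscretizer(TransformerMixin, BaseEstimator):
    """Per-feature MDL entropy discretizer (supervised).

    ``fit`` learns cut points per column from the training samples;
    ``transform`` maps values to interval indices for the half-open
    intervals ``(-inf, c1), [c1, c2), ..., [cm, inf)``.  Features with no
    accepted cut map every value (training or new) to interval 0.

    Parameters
    ----------
    max_cuts : int or None
        Global cap on accepted cuts per feature; ``1`` restricts to a
        single binary split, ``None`` (default) runs the full recursion.
    """

    def __init__(self, max_cuts: int | None = None):
        self.max_cuts = max_cuts

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.cuts_ = [
            mdl_discretize(X[:, j], y, max_cuts=self.max_cuts)
            for j in range(X.shape[1])
        ]
        self.n_bins_ = np.asarray([c.size + 1 for c in self.cuts_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "cuts_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, discretizer was fitted with "
                f"{self.n_features_in_}"
            )
        out = np.empty_like(X, dtype=float)
        for j, cuts in enumerate(self.cuts_):
            out[:, j] = assign_intervals(X[:, j], cuts)
        return out


class FeatureVectorAddition(TransformerMixin, BaseEstimator):
    """Sum all input features into one composite feature (raw values).

    The workbench applies this only to genes selected under an up- or
    down-regulated pattern; the class itself is pattern-agnostic so it can
    be composed in ordinary sklearn pipelines.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, transformer was fitted with "
                f"{self.n_features_in_}"
            )
        return X.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# functional surface over FeatureBlock
# ----------------------------------------------------------------------

def fit_discretizer(block: FeatureBlock, labels, max_cuts: int | None = None) -> MDLDiscretizer:
    """Learn MDL cuts for every feature of a numeric block."""
    if block.encoding != "numeric":
        raise ValueError("discretizer must be fitted on numeric features")
    disc = MDLDiscretizer(max_cuts=max_cuts).fit(block.matrix.T, np.asarray(labels))
    disc.feature_names_ = block.names
    return disc


def apply_discretizer(disc: MDLDiscretizer, block: FeatureBlock) -> FeatureBlock:
    """Map a numeric block to interval indices using fitted cuts."""
    names = getattr(disc, "feature_names_", None)
    if names is not None and tuple(names) != tuple(block.names):
        raise ValueError(
            "feature mismatch: discretizer fitted on "
            f"{list(names)}, applied to {list(block.names)}"
        )
    coded = disc.transform(block.matrix.T).T
    return FeatureBlock(coded, block.names, encoding="interval-index", pattern=block.pattern)


def feature_vector_addition(block: FeatureBlock) -> FeatureBlock:
    """Sum a same-direction gene block into a single composite feature.

    Raises if the block was selected under the total pattern: the composite
    only makes sense when all genes share a direction.
    """
    if block.pattern not in ("up", "down"):
        raise ValueError(
            "feature vector addition requires up- or down-regulated selection"
        )
    composite = block.matrix.sum(axis=0, keepdims=True)
    name = f"fva({block.n_features} genes, {block.pattern})"
    return FeatureBlock(composite, (name,), encoding="numeric", pattern=block.pattern)
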