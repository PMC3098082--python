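"""The gene-selection procedure as a scikit-learn classifier.

:class:`ProcedureClassifier` bundles one complete procedure — statistic,
up/down pattern, top-k selection, optional MDL discretization, optional
feature-vector addition, and an SVM or random-forest back end — behind the
standard ``fit``/``predict`` contract.  Crucially, gene selection happens
inside ``fit``, so resampling-based error estimators (the .632+ bootstrap
here, or sklearn's own cross-validation) automatically re-run selection on
every training set and therefore measure the whole procedure, not just the
final classifier.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .classification import ClassifierSpec, make_classifier
from .feature_selection import (
    direction_calls,
    info_gain_scores,
    rank_sum_scores,
    welch_t_scores,
)
from .transforms import MDLDiscretizer

__all__ = ["ProcedureClassifier"]

STATISTICS = ("ttest", "wilcoxon", "infogain")
PATTERNS = ("total", "up", "down")
CLASSIFIERS = ("svm", "random_forest")


class ProcedureClassifier(ClassifierMixin, BaseEstimator):
    """One gene-selection procedure as a fit/predict classifier.

    Parameters
    ----------
    statistic : {"ttest", "wilcoxon", "infogain"}
        Gene-ranking statistic.  ``ttest`` is Welch's two-sample t ranked by
        ascending p; ``wilcoxon`` the Mann-Whitney U ranked by ascending p;
        ``infogain`` information gain in bits under MDL discretization,
        ranked descending.
    pattern : {"total", "up", "down"}
        Candidate pool: all genes, or only genes up-/down-regulated in the
        positive class.
    k : int
        Number of genes to select (fewer are used, and ``truncated_`` set,
        when the pool is smaller).
    discretize : bool
        Replace classifier inputs by MDL interval indices (cuts learned on
        the training samples).
    fva : bool
        Feature-vector addition: sum the k selected same-direction genes
        into one composite feature.  Requires ``pattern`` in {"up", "down"}.
        With ``discretize=True`` the composite is formed first, then
        discretized.
    classifier : {"svm", "random_forest"}
        Back-end learner (RBF SVM with standardization, or a 500-tree
        random forest).
    positive_class : optional
        Label treated as class 1 for direction calls; defaults to the
        smaller label under numpy's sort order (lexicographic for strings).
    fva_mode : {"replace", "append"}
        Whether the composite replaces the k gene features (default) or is
        appended to them.
    random_state : int, optional
        Seed for the random forest.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels seen in ``fit``.
    selected_idx_ : ndarray
        Column indices of the selected genes, in rank order.
    selected_genes_ : list of str
        Names of the selected genes (column indices as strings when the
        input carried no feature names).
    truncated_ : bool
        True when the pattern pool held fewer than k genes.
    scores_ : dict
        Arrays of the per-gene statistic/p-value/direction used for ranking.
    """

    def __init__(
        self,
        statistic: str = "ttest",
        pattern: str = "total",
        k: int = 10,
        discretize: bool = False,
        fva: bool = False,
        classifier: str = "svm",
        positive_class=None,
        fva_mode: str = "replace",
        svm_c: float = 1.0,
        svm_gamma="auto",
        rf_trees: int = 500,
        rf_max_features="sqrt",
        mdl_max_cuts: int | None = None,
        random_state: int | None = None,
    ):
        self.statistic = statistic
        self.pattern = pattern
        self.k = k
        self.discretize = discretize
        self.fva = fva
        self.classifier = classifier
        self.positive_class = positive_class
        self.fva_mode = fva_mode
        self.svm_c = svm_c
        self.svm_gamma = svm_gamma
        self.rf_trees = rf_trees
        self.rf_max_features = rf_max_features
        self.mdl_max_cuts = mdl_max_cuts
        self.random_state = random_state

    # -- fitting --------------------------------------------------------
    def _validate_params_strict(self):
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.fva_mode not in ("replace", "append"):
            raise ValueError("fva_mode must be 'replace' or 'append'")
        if int(self.k) < 1:
            raise ValueError("k must be >= 1")
        if self.fva and self.pattern == "total":
            raise ValueError(
                "feature vector addition requires up- or down-regulated selection"
            )

    def fit(self, X, y):
        self._validate_params_strict()
        if hasattr(X, "columns"):
            self._feature_names = [str(c) for c in X.columns]
        else:
            self._feature_names = None
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"exactly two classes required, got {self.classes_.size}"
            )
        counts = np.asarray([(y == c).sum() for c in self.classes_])
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 training samples")
        pos = self.positive_class if self.positive_class is not None else self.classes_[0]
        if pos not in self.classes_:
            raise ValueError(f"positive_class {pos!r} not among classes")
        self.positive_class_ = pos
        self.n_features_in_ = X.shape[1]

        genes = X.T  # genes x samples
        pos_mask = y == pos
        directions = direction_calls(genes, pos_mask)
        if self.statistic == "ttest":
            t, p = welch_t_scores(genes, pos_mask)
            keys = list(zip(p, -np.abs(t), range(len(p))))
            self.scores_ = {"statistic": t, "p_value": p, "direction": directions}
        elif self.statistic == "wilcoxon":
            u, p = rank_sum_scores(genes, pos_mask)
            center = pos_mask.sum() * (~pos_mask).sum() / 2.0
            keys = list(zip(p, -np.abs(u - center), range(len(p))))
            self.scores_ = {"statistic": u, "p_value": p, "direction": directions}
        else:
            gains, _ = info_gain_scores(genes, y, max_cuts=self.mdl_max_cuts)
            keys = list(zip(-gains, np.zeros_like(gains), range(len(gains))))
            self.scores_ = {"statistic": gains, "p_value": None, "direction": directions}

        if self.pattern == "total":
            pool = np.arange(X.shape[1])
        else:
            pool = np.nonzero(directions == self.pattern)[0]
        if pool.size == 0:
            raise ValueError(f"no genes in pattern group {self.pattern!r}")
        ranked = sorted(pool, key=lambda i: keys[i])
        k = int(self.k)
        self.selected_idx_ = np.asarray(ranked[:k], dtype=int)
        self.truncated_ = pool.size < k
        if self._feature_names is not None:
            self.selected_genes_ = [self._feature_names[i] for i in self.selected_idx_]
        else:
            self.selected_genes_ = [str(i) for i in self.selected_idx_]

        feats = X[:, self.selected_idx_]
        if self.fva:
            composite = feats.sum(axis=1, keepdims=True)
            feats = composite if self.fva_mode == "replace" else np.hstack([feats, composite])
        if self.discretize:
            self.discretizer_ = MDLDiscretizer(max_cuts=self.mdl_max_cuts).fit(feats, y)
            feats = self.discretizer_.transform(feats)
        else:
            self.discretizer_ = None

        seed = 0 if self.random_state is None else int(self.random_state)
        spec = ClassifierSpec(
            kind=self.classifier,
            seed=seed,
            svm_c=self.svm_c,
            svm_gamma=self.svm_gamma,
            n_trees=self.rf_trees,
            max_features=self.rf_max_features,
        )
        self.model_ = make_classifier(spec).fit(feats, y)
        return self

    # -- prediction -----------------------------------------------------
    def _transform(self, X):
        feats = X[:, self.selected_idx_]
        if self.fva:
            composite = feats.sum(axis=1, keepdims=True)
            feats = composite if self.fva_mode == "replace" else np.hstack([feats, composite])
        if self.discretizer_ is not None:
            feats = self.discretizer_.transform(feats)
        return feats

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, fit saw {self.n_features_in_}"
            )
        if X.shape[0] == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.model_.predict(self._transform(X))
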