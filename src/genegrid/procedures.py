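"""Procedure specifications: one point of the workbench grid."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .estimator import CLASSIFIERS, PATTERNS, STATISTICS, ProcedureClassifier

__all__ = ["ProcedureSpec"]


@dataclass(frozen=True)
class ProcedureSpec:
    """A gene-selection procedure: statistic, pattern, k, transforms, classifier.

    Feature-vector addition is only meaningful when genes share a
    direction, so ``fva=True`` requires an up or down pattern.
    """

    fs_method: str  # ttest | wilcoxon | infogain
    pattern: str  # total | up | down
    k: int
    discretize: bool
    fva: bool
    classifier: str  # svm | random_forest

    def __post_init__(self):
        if self.fs_method not in STATISTICS:
            raise ValueError(f"fs_method must be one of {STATISTICS}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if int(self.k) < 1:
            raise ValueError("k must be >= 1")
        if self.fva and self.pattern == "total":
            raise ValueError(
                "feature vector addition requires up- or down-regulated selection"
            )

    def to_estimator(
        self, positive_class=None, random_state: int | None = None, **overrides
    ) -> ProcedureClassifier:
        """Build the matching :class:`ProcedureClassifier`."""
        return ProcedureClassifier(
            statistic=self.fs_method,
            pattern=self.pattern,
            k=int(self.k),
            discretize=bool(self.discretize),
            fva=bool(self.fva),
            classifier=self.classifier,
            positive_class=positive_class,
            random_state=random_state,
            **overrides,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def label(self) -> str:
        """Short human-readable tag used in reports and logs."""
        opts = []
        if self.discretize:
            opts.append("disc")
        if self.fva:
            opts.append("fva")
        tail = "+" + "+".join(opts) if opts else ""
        return f"{self.fs_method}/{self.pattern}/k={self.k}{tail}/{self.classifier}"
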