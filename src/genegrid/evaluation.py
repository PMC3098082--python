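""".632+ bootstrap evaluation of complete gene-selection procedures.

The estimator blends the optimistic resubstitution error err_bar with the
pessimistic leave-one-out bootstrap error err1 using a weight driven by the
relative overfitting rate R:

    gamma    = sum_c p_c (1 - q_c)            (no-information error rate)
    err1'    = min(err1, gamma)
    R        = (err1' - err_bar) / (gamma - err_bar)   if err1' > err_bar
               and gamma > err_bar, else 0; clipped to [0, 1]
    w        = 0.632 / (1 - 0.368 R)
    Err.632+ = (1 - w) err_bar + w err1'

Every bootstrap replicate re-runs the *entire* procedure — gene ranking,
direction filtering, top-k selection, transforms and classifier training —
on the in-bag samples only, then predicts the out-of-bag samples.  Running
selection outside the resample would leak the held-out labels into the gene
list and bias the estimate down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionDataset
from .procedures import ProcedureSpec

__all__ = [
    "BootstrapPlan",
    "BootstrapEstimate",
    "ProcedureResult",
    "derive_seed",
    "bootstrap_resample",
    "resubstitution_error",
    "no_information_rate",
    "err632plus",
    "loo_bootstrap_error",
    "evaluate_procedure",
]


def derive_seed(*parts: int) -> int:
    """Deterministic 31-bit seed from integer parts (schedule-independent)."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class BootstrapPlan:
    """Replicate count, master seed and the degenerate-resample redraw cap."""

    B: int = 100
    master_seed: int = 0
    max_redraws: int = 50

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.max_redraws < 1:
            raise ValueError("max_redraws must be >= 1")


@dataclass(frozen=True)
class BootstrapEstimate:
    """All quantities of the .632+ estimator for one procedure."""

    err_bar: float
    err1: float
    gamma: float
    R: float
    w: float
    err632plus: float
    n_oob_excluded: int = 0


@dataclass(frozen=True)
class ProcedureResult:
    """A procedure, its .632+ estimate and its full-data gene list."""

    spec: ProcedureSpec
    estimate: BootstrapEstimate | None
    genes: tuple[str, ...]
    truncated: bool
    status: str  # "ok" | "truncated-k" | "failed:<msg>"
    canonical_index: int = 0

    @property
    def ok(self) -> bool:
        return not self.status.startswith("failed")


def bootstrap_resample(
    n: int, labels, plan: BootstrapPlan, r: int
) -> tuple[np.ndarray, np.ndarray]:
    """In-bag multiset (n draws with replacement) and out-of-bag index set.

    Replicate r draws from a generator seeded by (master_seed, r); if the
    in-bag set does not contain at least two samples of each class the draw
    is repeated with the next derived seed, up to ``plan.max_redraws``
    times.  Two per class (not merely one) are required because the scoring
    statistics inside the resampled procedure need class variances/ranks.
    """
    if n < 4:
        raise ValueError("need at least 4 samples to bootstrap")
    y = np.asarray(labels)
    classes = np.unique(y)
    for attempt in range(plan.max_redraws):
        rng = np.random.default_rng(
            np.random.SeedSequence([plan.master_seed, int(r), attempt])
        )
        in_bag = rng.integers(0, n, size=n)
        counts = [(y[in_bag] == c).sum() for c in classes]
        if min(counts) >= 2:
            oob = np.setdiff1d(np.arange(n), in_bag)
            return in_bag, oob
    raise RuntimeError(
        f"replicate {r}: {plan.max_redraws} redraws without >= 2 in-bag samples "
        f"per class (class counts {dict(zip(map(str, classes), np.bincount(np.searchsorted(classes, y))))})"
    )


def _fit_full(spec: ProcedureSpec, ds: ExpressionDataset, seed: int, **overrides):
    est = spec.to_estimator(
        positive_class=ds.positive_class, random_state=seed, **overrides
    )
    X = ds.matrix.T
    y = ds.label_array
    est.fit(X, y)
    return est, np.asarray(est.predict(X)), y


def resubstitution_error(
    spec: ProcedureSpec, ds: ExpressionDataset, seed: int = 0, **overrides
) -> float:
    """Error of the full procedure trained and evaluated on all samples."""
    _, pred, y = _fit_full(spec, ds, seed, **overrides)
    return float(np.mean(pred != y))


def no_information_rate(labels, predictions) -> float:
    """gamma = sum over classes of p_c (1 - q_c).

    p_c is the observed class proportion and q_c the proportion of samples
    the resubstitution model predicts as class c; gamma is the expected
    error were labels and predictions independent.
    """
    y = np.asarray(labels)
    pred = np.asarray(predictions)
    classes = np.unique(y)
    n = y.size
    gamma = 0.0
    for c in classes:
        p_c = (y == c).sum() / n
        q_c = (pred == c).sum() / n
        gamma += p_c * (1.0 - q_c)
    return float(gamma)


def err632plus(err_bar: float, err1: float, gamma: float) -> tuple[float, float, float]:
    """(R, w, Err.632+) from the three error rates, all in [0, 1]."""
    for name, v in (("err_bar", err_bar), ("err1", err1), ("gamma", gamma)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    err1p = min(err1, gamma)
    if err1p > err_bar and gamma > err_bar:
        R = (err1p - err_bar) / (gamma - err_bar)
    else:
        R = 0.0
    R = min(max(R, 0.0), 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    return R, w, (1.0 - w) * err_bar + w * err1p


@dataclass(frozen=True)
class LooBootstrapResult:
    err1: float
    n_oob_excluded: int
    replicate_selections: tuple[tuple[str, ...], ...] | None = None


def loo_bootstrap_error(
    spec: ProcedureSpec,
    ds: ExpressionDataset,
    plan: BootstrapPlan,
    collect_selections: bool = False,
    **overrides,
) -> LooBootstrapResult:
    """Leave-one-out bootstrap error of the whole procedure.

    For each replicate the procedure is refitted from scratch on the in-bag
    samples and its out-of-bag misclassifications recorded; err1 averages
    each sample's own out-of-bag error rate, then averages over samples.
    Samples that were never out-of-bag are excluded from the outer mean and
    counted in ``n_oob_excluded``.
    """
    n = ds.n_samples
    X = ds.matrix.T
    y = ds.label_array
    errors = np.zeros(n)
    appearances = np.zeros(n)
    selections: list[tuple[str, ...]] = []
    for r in range(plan.B):
        in_bag, oob = bootstrap_resample(n, y, plan, r)
        if oob.size == 0:
            continue
        est = spec.to_estimator(
            positive_class=ds.positive_class,
            random_state=derive_seed(plan.master_seed, r, 1),
            **overrides,
        )
        est.fit(X[in_bag], y[in_bag])
        if collect_selections:
            selections.append(tuple(ds.gene_ids[i] for i in est.selected_idx_))
        pred = np.asarray(est.predict(X[oob]))
        errors[oob] += pred != y[oob]
        appearances[oob] += 1
    seen = appearances > 0
    if not seen.any():
        raise RuntimeError(
            "no sample was ever out-of-bag; increase the number of replicates B"
        )
    err1 = float(np.mean(errors[seen] / appearances[seen]))
    return LooBootstrapResult(
        err1=err1,
        n_oob_excluded=int((~seen).sum()),
        replicate_selections=tuple(selections) if collect_selections else None,
    )


def evaluate_procedure(
    spec: ProcedureSpec,
    ds: ExpressionDataset,
    plan: BootstrapPlan,
    canonical_index: int = 0,
    collect_selections: bool = False,
    **overrides,
) -> ProcedureResult:
    """Full .632+ evaluation of one procedure plus its full-data gene list."""
    full_seed = derive_seed(plan.master_seed, 0, 0)
    est, pred, y = _fit_full(spec, ds, full_seed, **overrides)
    err_bar = float(np.mean(pred != y))
    gamma = no_information_rate(y, pred)
    loo = loo_bootstrap_error(
        spec, ds, plan, collect_selections=collect_selections, **overrides
    )
    R, w, e632p = err632plus(err_bar, loo.err1, gamma)
    estimate = BootstrapEstimate(
        err_bar=err_bar,
        err1=loo.err1,
        gamma=gamma,
        R=R,
        w=w,
        err632plus=e632p,
        n_oob_excluded=loo.n_oob_excluded,
    )
    genes = tuple(ds.gene_ids[i] for i in est.selected_idx_)
    status = "truncated-k" if est.truncated_ else "ok"
    result = ProcedureResult(
        spec=spec,
        estimate=estimate,
        genes=genes,
        truncated=bool(est.truncated_),
        status=status,
        canonical_index=canonical_index,
    )
    if collect_selections:
        object.__setattr__(result, "replicate_selections", loo.replicate_selections)
    return result
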