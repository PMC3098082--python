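"""Differential-expression gene ranking and top-k selection.

Three statistics are supported: Welch's two-sample t (parametric), the
Wilcoxon rank-sum / Mann-Whitney U (non-parametric), and information gain
under MDL entropy discretization (model-free).  Each gene additionally gets
an up/down direction call relative to the dataset's positive class, so that
selection can be restricted to up- or down-regulated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import ExpressionDataset
from .mdl import information_gain, mdl_discretize

__all__ = [
    "GeneScore",
    "Selection",
    "score_ttest",
    "score_wilcoxon",
    "score_infogain",
    "assign_direction",
    "select_top_k",
    "welch_t_scores",
    "rank_sum_scores",
    "info_gain_scores",
]


@dataclass(frozen=True)
class GeneScore:
    """Per-gene ranking record for one statistic."""

    gene_id: str
    statistic: float
    p_value: float | None
    info_gain: float | None
    direction: str  # "up" | "down"
    rank_key: tuple

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")


@dataclass(frozen=True)
class Selection:
    """Result of top-k selection within a pattern group."""

    gene_ids: tuple[str, ...]
    pattern: str
    k: int
    truncated: bool


# ----------------------------------------------------------------------
# vectorized scoring kernels (X is genes x samples)
# ----------------------------------------------------------------------

def welch_t_scores(x: np.ndarray, pos_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t statistic and two-sided p per row.

    Degenerate rows (zero variance in both classes, equal means) get
    ``t = 0, p = 1``; zero variance with unequal means gives ``|t| = inf,
    p = 0``.
    """
    x = np.asarray(x, dtype=float)
    a, b = x[:, pos_mask], x[:, ~pos_mask]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trigger scipy's catastrophic-cancellation warning;
        # those rows are overwritten by the degenerate-gene rule below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    flat = degenerate & (diff == 0)
    sep = degenerate & (diff != 0)
    t[flat], p[flat] = 0.0, 1.0
    t[sep] = np.where(diff[sep] > 0, np.inf, -np.inf)
    p[sep] = 0.0
    bad = ~np.isfinite(p)
    t[bad], p[bad] = 0.0, 1.0
    return t, p


def rank_sum_scores(
    x: np.ndarray, pos_mask: np.ndarray, exact_max_n: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Mann-Whitney U (for the positive class) and two-sided p per row.

    The exact null distribution is used when ``min(n1, n2) <= exact_max_n``
    and the row has no ties; otherwise the normal approximation with tie
    and continuity corrections.  Rows constant across both classes get
    ``U = n1 n2 / 2, p = 1``.
    """
    x = np.asarray(x, dtype=float)
    a, b = x[:, pos_mask], x[:, ~pos_mask]
    n1, n2 = a.shape[1], b.shape[1]
    u = np.empty(x.shape[0])
    p = np.empty(x.shape[0])
    constant = np.ptp(x, axis=1) == 0
    u[constant], p[constant] = n1 * n2 / 2.0, 1.0
    todo = ~constant
    if min(n1, n2) > exact_max_n:
        if todo.any():
            res = stats.mannwhitneyu(
                a[todo], b[todo], axis=1, alternative="two-sided",
                method="asymptotic", use_continuity=True,
            )
            u[todo], p[todo] = res.statistic, res.pvalue
        return u, p
    for i in np.nonzero(todo)[0]:
        row = x[i]
        method = "exact" if np.unique(row).size == row.size else "asymptotic"
        res = stats.mannwhitneyu(
            a[i], b[i], alternative="two-sided", method=method, use_continuity=True
        )
        u[i], p[i] = res.statistic, res.pvalue
    return u, p


def info_gain_scores(
    x: np.ndarray, labels: np.ndarray, max_cuts: int | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Information gain in bits per row, with the MDL cuts that produced it."""
    x = np.asarray(x, dtype=float)
    gains = np.empty(x.shape[0])
    cut_lists: list[np.ndarray] = []
    for i, row in enumerate(x):
        cuts = mdl_discretize(row, labels, max_cuts=max_cuts)
        cut_lists.append(cuts)
        gains[i] = information_gain(row, labels, cuts) if cuts.size else 0.0
    return gains, cut_lists


def direction_calls(x: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """'up' where the positive-class mean exceeds the other class, else 'down'.

    Exactly equal means are called 'down' (documented, deterministic tie rule).
    """
    diff = x[:, pos_mask].mean(axis=1) - x[:, ~pos_mask].mean(axis=1)
    return np.where(diff > 0, "up", "down")


# ----------------------------------------------------------------------
# dataset-level operations
# ----------------------------------------------------------------------

def assign_direction(ds: ExpressionDataset) -> np.ndarray:
    """Per-gene up/down call relative to ``ds.positive_class``."""
    return direction_calls(ds.matrix, ds.positive_mask())


def _build_scores(ds, stat, p, gain, key_fn) -> list[GeneScore]:
    directions = assign_direction(ds)
    out = []
    for i, gid in enumerate(ds.gene_ids):
        out.append(
            GeneScore(
                gene_id=gid,
                statistic=float(stat[i]),
                p_value=None if p is None else float(p[i]),
                info_gain=None if gain is None else float(gain[i]),
                direction=str(directions[i]),
                rank_key=key_fn(i),
            )
        )
    return out


def score_ttest(ds: ExpressionDataset) -> list[GeneScore]:
    """Welch t scores in gene file order; rank key = (p asc, |t| desc, index)."""
    _require_two_per_class(ds)
    t, p = welch_t_scores(ds.matrix, ds.positive_mask())
    return _build_scores(ds, t, p, None, lambda i: (p[i], -abs(t[i]), i))


def score_wilcoxon(ds: ExpressionDataset) -> list[GeneScore]:
    """Rank-sum scores; rank key = (p asc, |U - n1 n2 / 2| desc, index)."""
    _require_two_per_class(ds)
    mask = ds.positive_mask()
    u, p = rank_sum_scores(ds.matrix, mask)
    center = mask.sum() * (~mask).sum() / 2.0
    return _build_scores(ds, u, p, None, lambda i: (p[i], -abs(u[i] - center), i))


def score_infogain(ds: ExpressionDataset) -> list[GeneScore]:
    """Information-gain scores; rank key = (gain desc, index)."""
    _require_two_per_class(ds)
    gains, _ = info_gain_scores(ds.matrix, ds.label_array)
    return _build_scores(ds, gains, None, gains, lambda i: (-gains[i], i))


def _require_two_per_class(ds: ExpressionDataset) -> None:
    mask = ds.positive_mask()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each class needs at least 2 samples for scoring")


def select_top_k(scores: list[GeneScore], pattern: str, k: int) -> Selection:
    """Top-k gene ids within a pattern group, in rank order.

    ``pattern='total'`` uses all genes; ``'up'``/``'down'`` restrict to that
    direction first.  When the group holds fewer than k genes all of them
    are returned and the selection is flagged truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if pattern not in ("total", "up", "down"):
        raise ValueError(f"pattern must be total/up/down, got {pattern!r}")
    group = scores if pattern == "total" else [s for s in scores if s.direction == pattern]
    ranked = sorted(group, key=lambda s: s.rank_key)
    chosen = ranked[:k]
    return Selection(
        gene_ids=tuple(s.gene_id for s in chosen),
        pattern=pattern,
        k=k,
        truncated=len(group) < k,
    )


def scores_to_table(scores: list[GeneScore]):
    """Scores as a DataFrame (gene_id, statistic, p_value, info_gain, direction, rank)."""
    import pandas as pd

    order = sorted(range(len(scores)), key=lambda i: scores[i].rank_key)
    rank = {i: r + 1 for r, i in enumerate(order)}
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "statistic": [s.statistic for s in scores],
            "p_value": [s.p_value for s in scores],
            "info_gain": [s.info_gain for s in scores],
            "direction": [s.direction for s in scores],
            "rank": [rank[i] for i in range(len(scores))],
        }
    )
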