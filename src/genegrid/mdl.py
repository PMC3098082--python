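"""Entropy-based discretization with the Fayyad–Irani MDL stopping rule.

A continuous feature is partitioned by recursive binary splitting: at each
node the cut minimizing the class-entropy of the two halves is proposed and
accepted only if its information gain exceeds the minimum-description-length
cost of encoding the extra partition.  Cuts are placed at midpoints between
adjacent distinct values; all entropies are in bits.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

__all__ = ["mdl_discretize", "information_gain", "entropy_bits", "assign_intervals"]


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a class-count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts / total
    return float(-(xlogy(p, p).sum()) / np.log(2))


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Row-wise entropy in bits of an (m, c) count array."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return -(xlogy(p, p).sum(axis=1)) / np.log(2)


def _recurse(v: np.ndarray, cum: np.ndarray, lo: int, hi: int,
             cuts: list[float], budget: list[int]) -> None:
    """Split the sorted slice [lo, hi) if the MDL criterion accepts a cut."""
    n = hi - lo
    if n < 2 or budget[0] == 0:
        return
    total = cum[hi] - cum[lo]
    h_parent = entropy_bits(total)
    if h_parent == 0.0:
        return  # class-pure slice: nothing to gain
    # candidate boundaries: positions where the sorted value changes
    idx = lo + 1 + np.nonzero(v[lo + 1:hi] > v[lo:hi - 1])[0]
    if idx.size == 0:
        return  # constant slice
    left = cum[idx] - cum[lo]
    right = total - left
    n_left = left.sum(axis=1)
    n_right = n - n_left
    h_left = _entropy_rows(left)
    h_right = _entropy_rows(right)
    weighted = (n_left * h_left + n_right * h_right) / n
    best = int(np.argmin(weighted))  # leftmost minimizer: deterministic
    gain = h_parent - weighted[best]

    k = int(np.count_nonzero(total))
    k1 = int(np.count_nonzero(left[best]))
    k2 = int(np.count_nonzero(right[best]))
    delta = np.log2(3.0**k - 2.0) - (k * h_parent - k1 * h_left[best] - k2 * h_right[best])
    threshold = (np.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    pos = int(idx[best])
    cuts.append(float((v[pos - 1] + v[pos]) / 2.0))
    if budget[0] > 0:
        budget[0] -= 1
    _recurse(v, cum, lo, pos, cuts, budget)
    _recurse(v, cum, pos, hi, cuts, budget)


def mdl_discretize(values, labels, max_cuts: int | None = None) -> np.ndarray:
    """Fayyad–Irani MDL cut points for one feature.

    Parameters
    ----------
    values : array-like of shape (n,)
        Continuous feature values, n >= 2.
    labels : array-like of shape (n,)
        Class labels (any hashable values).
    max_cuts : int, optional
        Global cap on the number of accepted cuts (``1`` gives single-split
        mode); ``None`` means full recursion.

    Returns
    -------
    ndarray
        Strictly increasing cut points; empty when no split passes the MDL
        test (constant features and single-class labellings included).
    """
    v = np.asarray(values, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if v.size != y.size:
        raise ValueError("values and labels must have equal length")
    if v.size < 2:
        raise ValueError("need at least 2 values to discretize")
    _, codes = np.unique(y, return_inverse=True)
    n_classes = codes.max() + 1
    order = np.argsort(v, kind="stable")
    v_sorted = v[order]
    onehot = np.zeros((v.size, n_classes))
    onehot[np.arange(v.size), codes[order]] = 1.0
    cum = np.zeros((v.size + 1, n_classes))
    np.cumsum(onehot, axis=0, out=cum[1:])
    cuts: list[float] = []
    budget = [-1 if max_cuts is None else int(max_cuts)]
    _recurse(v_sorted, cum, 0, v.size, cuts, budget)
    return np.asarray(sorted(cuts), dtype=float)


def assign_intervals(values, cuts) -> np.ndarray:
    """Map values to interval indices for half-open intervals.

    With cuts ``c1 < ... < cm`` the intervals are ``(-inf, c1), [c1, c2),
    ..., [cm, inf)``; a value equal to a cut falls in the interval to its
    right.
    """
    return np.searchsorted(np.asarray(cuts, dtype=float),
                           np.asarray(values, dtype=float), side="right")


def information_gain(values, labels, cuts) -> float:
    """Class-entropy reduction (bits) of the partition induced by ``cuts``.

    IG = H(class) - sum_i (n_i / n) H(class | interval i).  Zero when the
    cut list is empty.
    """
    y = np.asarray(labels).ravel()
    _, codes = np.unique(y, return_inverse=True)
    n_classes = codes.max() + 1
    h_total = entropy_bits(np.bincount(codes, minlength=n_classes))
    cuts = np.asarray(cuts, dtype=float)
    if cuts.size == 0:
        return 0.0
    bins = assign_intervals(values, cuts)
    n = y.size
    cond = 0.0
    for b in np.unique(bins):
        counts = np.bincount(codes[bins == b], minlength=n_classes)
        cond += counts.sum() / n * entropy_bits(counts)
    return float(h_total - cond)
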