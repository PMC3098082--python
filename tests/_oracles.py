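"""Independent, deliberately naive reference implementations used as test
oracles.  Everything here is plain-Python arithmetic (math.log2, explicit
loops, itertools enumeration) so that agreement with the fast numpy code
paths is a genuine cross-check, not a tautology."""

from __future__ import annotations

import itertools
import math
from collections import Counter


def entropy(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    h = 0.0
    for c in Counter(labels).values():
        p = c / n
        h -= p * math.log2(p)
    return h


def naive_info_gain(values, labels, cuts) -> float:
    """IG of the partition induced by cuts, via explicit interval grouping."""
    n = len(values)
    groups: dict[int, list] = {}
    for v, l in zip(values, labels):
        b = sum(1 for c in cuts if v >= c)  # half-open [c_i, c_{i+1}) convention
        groups.setdefault(b, []).append(l)
    cond = sum(len(g) / n * entropy(g) for g in groups.values())
    return entropy(labels) - cond


def naive_mdl_cuts(values, labels):
    """Recursive Fayyad-Irani MDL discretization by exhaustive midpoint scan."""
    pairs = sorted(zip(values, labels), key=lambda t: t[0])
    cuts: list[float] = []
    _split(pairs, cuts)
    return sorted(cuts)


def _split(pairs, cuts) -> None:
    n = len(pairs)
    labels = [l for _, l in pairs]
    h_parent = entropy(labels)
    if n < 2 or h_parent == 0.0:
        return
    best = None  # (weighted_entropy, position)
    for i in range(1, n):
        if pairs[i][0] <= pairs[i - 1][0]:
            continue
        left = [l for _, l in pairs[:i]]
        right = [l for _, l in pairs[i:]]
        we = len(left) / n * entropy(left) + len(right) / n * entropy(right)
        if best is None or we < best[0]:
            best = (we, i)
    if best is None:
        return
    we, i = best
    gain = h_parent - we
    left = [l for _, l in pairs[:i]]
    right = [l for _, l in pairs[i:]]
    k, k1, k2 = len(set(labels)), len(set(left)), len(set(right))
    delta = math.log2(3**k - 2) - (
        k * h_parent - k1 * entropy(left) - k2 * entropy(right)
    )
    if gain <= (math.log2(n - 1) + delta) / n:
        return
    cuts.append((pairs[i - 1][0] + pairs[i][0]) / 2)
    _split(pairs[:i], cuts)
    _split(pairs[i:], cuts)


def rank_sum_u_pmf(n1: int, n2: int):
    """Exact null pmf of the Mann-Whitney U statistic (no ties).

    Dynamic programming over ranks: f[j, w] counts ways to choose j of the
    first r ranks with rank sum w; U = W - n1(n1+1)/2.  Returns an array of
    length n1*n2 + 1.
    """
    import numpy as np

    N = n1 + n2
    maxw = sum(range(N - n1 + 1, N + 1))
    f = np.zeros((n1 + 1, maxw + 1))
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(n1, r), 0, -1):
            f[j, r:] += f[j - 1, : maxw + 1 - r]
    offset = n1 * (n1 + 1) // 2
    counts = f[n1, offset : offset + n1 * n2 + 1]
    return counts / counts.sum()


def folded_u_pit(u_values, n1: int, n2: int, rng):
    """Exact-null randomized PIT of the folded statistic D = |U - n1 n2 / 2|.

    Because U is discrete, two-sided rank-sum p-values live on a shared
    lattice and are only uniform *on their attainable atoms*; the
    randomized probability integral transform of D is exactly Uniform(0,1)
    under the null, so a KS test on it has its nominal level.  p is a
    strictly decreasing function of D, hence p-value calibration and
    D-calibration are the same statement.
    """
    import numpy as np

    pmf = rank_sum_u_pmf(n1, n2)
    c = n1 * n2 / 2.0
    d_of_u = np.abs(np.arange(n1 * n2 + 1) - c)
    d_atoms = np.unique(d_of_u)
    pmf_d = np.array([pmf[d_of_u == d].sum() for d in d_atoms])
    cdf_prev = np.concatenate([[0.0], np.cumsum(pmf_d)[:-1]])
    u_values = np.asarray(u_values)
    d_obs = np.abs(u_values - c)
    idx = np.searchsorted(d_atoms, d_obs)
    if not np.allclose(d_atoms[idx], d_obs):
        raise ValueError("observed U off the exact lattice (ties present?)")
    return cdf_prev[idx] + rng.uniform(size=u_values.size) * pmf_d[idx]


def exact_wilcoxon_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every rank assignment.

    Assumes no ties.  p = fraction of all C(n1+n2, n1) label placements
    whose U is at least as far from n1 n2 / 2 as the observed U.
    """
    combined = sorted(x) + sorted(y)
    assert len(set(combined)) == len(combined), "oracle requires no ties"
    n1, n2 = len(x), len(y)
    values = sorted(combined)

    def u_of(group):
        # U = number of (a, b) pairs with a > b, a in group
        rest = [v for v in values if v not in group]
        return sum(1 for a in group for b in rest if a > b)

    center = n1 * n2 / 2
    observed = abs(u_of(set(x)) - center)
    total = 0
    extreme = 0
    for subset in itertools.combinations(values, n1):
        total += 1
        if abs(u_of(set(subset)) - center) >= observed - 1e-12:
            extreme += 1
    return extreme / total
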