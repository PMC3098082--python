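import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genegrid.feature_selection import (
    assign_direction,
    rank_sum_scores,
    score_infogain,
    score_ttest,
    score_wilcoxon,
    select_top_k,
    welch_t_scores,
)
from conftest import make_dataset
from _oracles import exact_wilcoxon_p


class TestWelch:
    def test_matches_hand_computed_welch_formula(self):
        # class1 = (10,11,12), class2 = (1,2,3): equal unit variances,
        # t = 9 / sqrt(1/3 + 1/3), Welch-Satterthwaite df = 4
        ds = make_dataset([[10, 11, 12, 1, 2, 3]], ["A"] * 3 + ["B"] * 3)
        s = score_ttest(ds)[0]
        t_hand = 9.0 / math.sqrt(2.0 / 3.0)
        assert s.statistic == pytest.approx(t_hand)
        assert s.p_value == pytest.approx(2 * stats.t.sf(t_hand, df=4))
        assert s.direction == "up"

    @pytest.mark.parametrize(
        "row",
        [[5, 5, 5, 5, 5, 5], [1, 2, 3, 1, 2, 3]],
        ids=["constant", "identical-classes"],
    )
    def test_no_difference_gives_t0_p1(self, row):
        ds = make_dataset([row], ["A"] * 3 + ["B"] * 3)
        s = score_ttest(ds)[0]
        assert (s.statistic, s.p_value) == (0.0, 1.0)

    def test_separated_constants_get_p0(self):
        t, p = welch_t_scores(np.array([[4.0, 4, 4, 1, 1, 1]]), np.array([True] * 3 + [False] * 3))
        assert p[0] == 0.0 and t[0] == np.inf


class TestWilcoxon:
    def test_fully_separated_small_sample_exact_p(self):
        # U = 0; 2 of the C(6,3) = 20 rank assignments are as extreme
        ds = make_dataset([[1, 2, 3, 4, 5, 6]], ["A"] * 3 + ["B"] * 3)
        s = score_wilcoxon(ds)[0]
        assert s.statistic == 0.0
        assert s.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_p1(self):
        ds = make_dataset([[1, 2, 3, 1, 2, 3]], ["A"] * 3 + ["B"] * 3)
        assert score_wilcoxon(ds)[0].p_value == 1.0

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_exact_p_matches_full_enumeration(self, data):
        """Exact small-sample p-values must equal brute-force enumeration of
        every rank assignment (n1, n2 <= 6, no ties)."""
        n1 = data.draw(st.integers(2, 6))
        n2 = data.draw(st.integers(2, 6))
        vals = data.draw(
            st.lists(
                st.integers(-100, 100), min_size=n1 + n2, max_size=n1 + n2, unique=True
            )
        )
        x = np.asarray([vals], dtype=float)
        mask = np.asarray([True] * n1 + [False] * n2)
        _, p = rank_sum_scores(x, mask)
        assert p[0] == pytest.approx(exact_wilcoxon_p(vals[:n1], vals[n1:]))

    @settings(deadline=None, max_examples=20)
    @given(
        vals=st.lists(st.floats(0.1, 50, allow_nan=False), min_size=8, max_size=8, unique=True),
        transform=st.sampled_from(["exp-ish", "cube", "affine"]),
    )
    def test_invariant_under_strictly_increasing_transforms(self, vals, transform):
        fn = {
            "exp-ish": lambda v: np.expm1(v / 10.0),
            "cube": lambda v: v**3,
            "affine": lambda v: 3.0 * v + 7.0,
        }[transform]
        mask = np.asarray([True] * 4 + [False] * 4)
        x = np.asarray([vals], dtype=float)
        u0, p0 = rank_sum_scores(x, mask)
        u1, p1 = rank_sum_scores(fn(x), mask)
        assert u0[0] == u1[0] and p0[0] == pytest.approx(p1[0])


class TestInfoGain:
    def test_perfect_separator_scores_one_bit(self):
        ds = make_dataset([[1, 1, 2, 2, 8, 8, 9, 9]], ["A"] * 4 + ["B"] * 4)
        assert score_infogain(ds)[0].statistic == pytest.approx(1.0)

    def test_constant_gene_scores_zero(self):
        ds = make_dataset([[3.0] * 8], ["A"] * 4 + ["B"] * 4)
        assert score_infogain(ds)[0].statistic == 0.0

    def test_ordering_invariant_under_monotone_transform(self, signal_ds):
        ds, _ = signal_ds
        sub = make_dataset(ds.matrix[:40], ds.labels)
        mono = make_dataset(np.exp(sub.matrix / 4.0), ds.labels)
        order = lambda scores: [s.rank_key for s in scores]
        r0 = sorted(range(40), key=lambda i: score_infogain(sub)[i].rank_key)
        r1 = sorted(range(40), key=lambda i: score_infogain(mono)[i].rank_key)
        assert r0 == r1
        w0 = sorted(range(40), key=lambda i: score_wilcoxon(sub)[i].rank_key)
        w1 = sorted(range(40), key=lambda i: score_wilcoxon(mono)[i].rank_key)
        assert w0 == w1


class TestDirection:
    def test_direction_calls_and_tie_rule(self, tiny_ds):
        d = assign_direction(tiny_ds)
        assert list(d) == ["up", "down", "down"]  # exact tie -> down


class TestTopK:
    def _scores(self):
        ds = make_dataset(
            [[10, 11, 1, 2],  # strong up
             [1, 2, 10, 11],  # strong down
             [5.0, 6.1, 5.2, 6.0],  # weak
             [7, 8, 3, 4]],  # up
            ["A", "A", "B", "B"],
        )
        return ds, score_ttest(ds)

    def test_total_pattern_takes_smallest_p_first(self):
        _, scores = self._scores()
        sel = select_top_k(scores, "total", 2)
        assert not sel.truncated
        assert set(sel.gene_ids) <= {"g0", "g1", "g3"}

    def test_truncation_flagged_when_group_smaller_than_k(self):
        _, scores = self._scores()
        sel = select_top_k(scores, "up", 5)
        assert sel.truncated
        assert set(sel.gene_ids) == {"g0", "g3"}

    def test_ties_resolved_by_statistic_then_gene_index(self):
        ds = make_dataset(
            [[2, 3, 5, 6], [2, 3, 5, 6], [1, 2, 3, 4]], ["A", "A", "B", "B"]
        )
        scores = score_wilcoxon(ds)
        sel = select_top_k(scores, "total", 3)
        # g0 and g1 are exact duplicates: identical p and U, index breaks tie
        assert sel.gene_ids[:2] == ("g0", "g1") or sel.gene_ids == ("g0", "g1", "g2")

    def test_up_down_union_covers_total_selection(self, signal_ds):
        ds, _ = signal_ds
        scores = score_wilcoxon(ds)
        total = set(select_top_k(scores, "total", 15).gene_ids)
        up = set(select_top_k(scores, "up", 15).gene_ids)
        down = set(select_top_k(scores, "down", 15).gene_ids)
        assert total <= up | down

    def test_invalid_arguments_rejected(self):
        _, scores = self._scores()
        with pytest.raises(ValueError):
            select_top_k(scores, "total", 0)
        with pytest.raises(ValueError):
            select_top_k(scores, "sideways", 2)
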