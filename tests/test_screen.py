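"""AUC, rank tests, Benjamini-Hochberg, and the joint significance gate."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from palscreen.errors import StratumError
from palscreen.screen import (
    auc_two_group,
    bh_adjust,
    rank_test_p,
    screen_analytes,
)


def auc_pair_count_oracle(values, is_target):
    """Exhaustive enumeration of (target, rest) pairs; ties count one half."""
    values = np.asarray(values, float)
    tgt = values[np.asarray(is_target, bool)]
    rest = values[~np.asarray(is_target, bool)]
    wins = sum(1.0 if t > r else (0.5 if t == r else 0.0) for t in tgt for r in rest)
    return wins / (len(tgt) * len(rest))


def ranksum_exact_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


def bh_step_up_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestAUC:
    def test_perfect_separation(self):
        assert auc_two_group([1, 2, 3, 4], [False, False, True, True]) == 1.0

    def test_tie_handling_hand_count(self):
        got = auc_two_group([1, 2, 2, 3], [False, False, True, True])
        assert got == pytest.approx((1 + 1 + 0.5 + 1) / 4)  # 0.875

    def test_label_swap_symmetry(self, rng):
        vals = rng.normal(size=10)
        mask = np.array([True] * 4 + [False] * 6)
        assert auc_two_group(vals, mask) == pytest.approx(1 - auc_two_group(vals, ~mask))

    def test_empty_group_raises(self):
        with pytest.raises(StratumError):
            auc_two_group([1.0, 2.0], [True, True])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(600 + seed)
        n = int(rng.integers(4, 13))
        vals = rng.choice([0.0, 1.0, 2.0, 3.5, 7.0], size=n)
        mask = np.zeros(n, bool)
        mask[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        if mask.all() or not mask.any():
            mask[0] = ~mask[0]
        assert auc_two_group(vals, mask) == pytest.approx(auc_pair_count_oracle(vals, mask))


class TestRankTest:
    def test_identical_groups_no_evidence(self):
        assert rank_test_p([5.0] * 6, [True] * 3 + [False] * 3) == 1.0

    def test_strong_shift_tiny_p(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        p = rank_test_p(np.concatenate([a, b]), [False] * 50 + [True] * 50)
        assert p < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_small_n_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(700 + seed)
        vals = rng.permutation(np.arange(8, dtype=float))  # 4 vs 4, no ties
        mask = np.array([True] * 4 + [False] * 4)
        got = rank_test_p(vals, mask)
        assert got == pytest.approx(ranksum_exact_oracle(vals[mask], vals[~mask]))

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            rank_test_p([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)

    def test_paired_signed_rank(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x + np.array([0.5, 0.6, 0.4, 0.7, 0.5, 0.8])
        p = rank_test_p(y, x, paired=True)
        assert p == pytest.approx(stats.wilcoxon(y, x).pvalue)


class TestBH:
    def test_hand_step_up_three(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_hand_step_up_two(self):
        np.testing.assert_allclose(bh_adjust([0.05, 0.5]), [0.10, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_step_up_properties_hold_for_arbitrary_p_vectors(self, p):
        """q dominates p elementwise and is monotone along the sorted-p order."""
        p = np.asarray(p)
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_step_up_oracle(p), rtol=1e-12)
        assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_step_up_and_dominates_p(self, seed):
        rng = np.random.default_rng(800 + seed)
        p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_step_up_oracle(p), rtol=1e-12)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestScreenAnalytes:
    def _matrix(self, arr):
        return pd.DataFrame(arr, index=[f"a{i}" for i in range(len(arr))],
                            columns=[f"s{j}" for j in range(len(arr[0]))])

    def test_constant_analyte_neutral(self):
        m = self._matrix([[2.0] * 8])
        rec = screen_analytes(m, [True] * 4 + [False] * 4, "gene", "cancer_type_one_vs_rest")
        assert rec.loc[0, "auc_raw"] == 0.5
        assert rec.loc[0, "p"] == 1.0
        assert not rec.loc[0, "significant"]

    def test_empty_matrix_gives_empty_records(self):
        m = pd.DataFrame(np.empty((0, 6)), columns=[f"s{j}" for j in range(6)])
        rec = screen_analytes(m, [True] * 3 + [False] * 3, "gene", "tumor_vs_normal")
        assert len(rec) == 0

    def test_small_group_raises_with_stratum_name(self):
        m = self._matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(StratumError, match="C9"):
            screen_analytes(m, [True, False, False], "gene",
                            "cancer_type_one_vs_rest", cancer_type="C9")

    def test_planted_analyte_alone_is_flagged(self):
        rng = np.random.default_rng(11)
        n_target, n_rest = 30, 60
        null = rng.normal(0, 1, size=(99, n_target + n_rest))
        planted = np.concatenate([rng.normal(4, 1, n_target), rng.normal(0, 1, n_rest)])
        m = self._matrix(np.vstack([planted, null]))
        mask = np.array([True] * n_target + [False] * n_rest)
        rec = screen_analytes(m, mask, "gene", "cancer_type_one_vs_rest")
        hits = rec[rec["significant"]]["analyte"].tolist()
        assert hits == ["a0"]
        assert rec.loc[0, "auc_oriented"] > 0.95

    def test_invariant_to_sample_ordering(self, rng):
        vals = rng.normal(size=(5, 20))
        mask = np.array([True] * 8 + [False] * 12)
        m = self._matrix(vals)
        rec1 = screen_analytes(m, mask, "gene", "tumor_vs_normal")
        perm = rng.permutation(20)
        rec2 = screen_analytes(m.iloc[:, perm], mask[perm], "gene", "tumor_vs_normal")
        np.testing.assert_allclose(rec1["auc_raw"], rec2["auc_raw"])
        np.testing.assert_allclose(rec1["q"], rec2["q"])

    def test_q_dominates_p_and_significance_rule(self, rng):
        vals = rng.normal(size=(40, 30))
        vals[0, :10] += 3.0
        m = self._matrix(vals)
        mask = np.array([True] * 10 + [False] * 20)
        rec = screen_analytes(m, mask, "gene", "cancer_type_one_vs_rest")
        assert (rec["q"] >= rec["p"] - 1e-15).all()
        expected = (rec["auc_oriented"] > 0.7) & (rec["q"] < 0.05)
        assert (rec["significant"] == expected).all()
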