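"""Median-split survival screening: KM, log-rank, Cox fits and the joint gate."""

import numpy as np
import pandas as pd
import pytest

from palscreen.errors import CoxConvergenceError, StratumError
from palscreen.expression import ClinicalTable
from palscreen.survival import (
    STATUS_OK,
    STATUS_UNSPLITTABLE,
    cox_univariate,
    km_estimate,
    logrank_p,
    median_split,
    screen_survival,
)


def cox_grid_oracle(times, events, x, lo=-4.0, hi=4.0):
    """Brute-force maximization of the (tie-free) partial likelihood on a grid.

    Without ties the Efron and Breslow likelihoods coincide:
    l(b) = sum_deaths [ b*x_i - log sum_{t_j >= t_i} exp(b*x_j) ].
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    grid = np.arange(lo, hi, 1e-5)

    def loglik(b):
        ll = 0.0
        for i in np.where(events == 1)[0]:
            risk = times >= times[i]
            ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
        return ll

    vals = np.array([loglik(b) for b in grid])
    return grid[np.argmax(vals)]


class TestMedianSplit:
    def test_even_split(self):
        high = median_split([1, 2, 3, 4])
        assert list(high) == [False, False, True, True]

    def test_ties_go_low(self):
        high = median_split([1, 2, 2, 3])
        assert list(high) == [False, False, False, True]

    def test_constant_is_unsplittable(self):
        assert not median_split([5, 5, 5, 5]).any()


class TestKM:
    def test_all_censored_stays_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.shape == (0, 2)  # no steps -> S(t) = 1 throughout

    def test_two_events_hand_product(self):
        curve = km_estimate([1, 2], [1, 1])
        np.testing.assert_allclose(curve, [[1.0, 0.5], [2.0, 0.0]])

    def test_censor_then_event(self):
        curve = km_estimate([1, 2], [0, 1])
        np.testing.assert_allclose(curve, [[2.0, 0.0]])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_hand_product_limit(self, rng):
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(times, events)
        # independent product-limit loop over sorted distinct times
        surv = 1.0
        expected = []
        for t in np.unique(times):
            at_risk = int((times >= t).sum())
            d = int(((times == t) & (events == 1)).sum())
            if d > 0:
                surv *= 1.0 - d / at_risk
                expected.append((t, surv))
        np.testing.assert_allclose(curve, np.array(expected), atol=1e-12)
        assert (np.diff(curve[:, 1]) <= 0).all()
        assert ((curve[:, 1] >= 0) & (curve[:, 1] <= 1)).all()


class TestLogrank:
    def test_identical_groups_p_one(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        groups = [0, 0, 0, 1, 1, 1]
        assert logrank_p(times, events, groups) == pytest.approx(1.0)

    def test_hand_computed_six_subject_table(self):
        # group A: events at 1, 3; group B: event at 2, censored 2.5, events 4, 5
        times = [1.0, 3.0, 2.0, 2.5, 4.0, 5.0]
        events = [1, 1, 1, 0, 1, 1]
        groups = [True, True, False, False, False, False]
        # hand O-E/V over event times 1,2,3,4,5:
        # t=1: n=6,n1=2,d=1 -> e=1/3, v=(1)(2/6)(4/6)(5/5)=2/9
        # t=2: n=5,n1=1,d=1 -> e=1/5, v=(1/5)(4/5)=4/25
        # t=3: n=3,n1=1,d=1 -> e=1/3, v=(1/3)(2/3)=2/9
        # t=4: n=2,n1=0 -> 0 ; t=5: n=1,n1=0 -> 0
        o1, e1 = 2.0, 1 / 3 + 1 / 5 + 1 / 3
        v = 2 / 9 + 4 / 25 + 2 / 9
        from scipy.stats import chi2

        expected = chi2.sf((o1 - e1) ** 2 / v, 1)
        assert logrank_p(times, events, groups) == pytest.approx(expected, rel=1e-12)

    def test_zero_events_degenerate_p_one(self):
        assert logrank_p([1, 2, 3, 4], [0, 0, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_group_relabel_invariance(self, rng):
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        groups = rng.integers(0, 2, 30).astype(bool)
        events[0] = 1
        groups[:2] = [True, False]
        assert logrank_p(times, events, groups) == pytest.approx(
            logrank_p(times, events, ~groups)
        )

    def test_rate_ratio_three_detected(self):
        rng = np.random.default_rng(5)
        t1 = rng.exponential(1.0, 200)
        t2 = rng.exponential(3.0, 200)
        times = np.concatenate([t1, t2])
        events = np.ones(400, int)
        groups = np.array([True] * 200 + [False] * 200)
        assert logrank_p(times, events, groups) < 1e-4

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        times = rng.exponential(5, 50)
        events = rng.integers(0, 2, 50)
        groups = rng.integers(0, 2, 50).astype(bool)
        events[:2] = 1
        groups[:2] = [True, False]
        ours = logrank_p(times, events, groups)
        ref = logrank_test(times[groups], times[~groups],
                           events[groups], events[~groups]).p_value
        assert ours == pytest.approx(ref, rel=1e-9)


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1, 2, 3], [1, 1, 0], [1.0, 1.0, 1.0])

    def test_four_subject_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0]
        fit = cox_univariate(times, events, x)
        assert fit.beta == pytest.approx(cox_grid_oracle(times, events, x), abs=1e-4)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_lifelines_with_ties(self, seed):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(900 + seed)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        times = np.round(rng.exponential(10 * np.exp(-0.8 * x)), 1) + 0.1  # forced ties
        events = rng.integers(0, 2, n)
        events[:10] = 1
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        fit = cox_univariate(times, events, x)
        assert fit.beta == pytest.approx(float(ref.params_["x"]), abs=1e-6)
        assert fit.se == pytest.approx(float(ref.standard_errors_["x"]), abs=1e-6)

    def test_group_swap_gives_reciprocal_hr(self, rng):
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(np.exp(-0.5 * x), n)
        events = np.ones(n, int)
        a = cox_univariate(times, events, x)
        b = cox_univariate(times, events, 1.0 - x)
        assert abs(np.log(a.hr) + np.log(b.hr)) < 1e-8

    def test_planted_hr_two_recovered(self):
        rng = np.random.default_rng(77)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(np.exp(-np.log(2.0) * x), n)
        events = np.ones(n, int)
        fit = cox_univariate(times, events, x)
        assert fit.ci_low < 2.0 < fit.ci_high

    def test_monotone_likelihood_flagged(self):
        # complete separation: all group-1 events precede every group-0 event
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 1, 1, 1]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        with pytest.raises(CoxConvergenceError):
            cox_univariate(times, events, x)


def _clinical(times, events, n, prefix="T"):
    ids = [f"{prefix}{i}" for i in range(n)]
    return ClinicalTable(pd.DataFrame({
        "cancer_type": "C1", "tissue": "tumor",
        "os_time": times, "os_event": events,
        "pfs_time": np.nan, "pfs_event": np.nan,
    }, index=ids)), ids


class TestScreenSurvival:
    def test_empty_matrix_gives_empty_records(self):
        clin, ids = _clinical(np.arange(1.0, 11.0), np.ones(10), 10)
        m = pd.DataFrame(index=pd.Index([], name="a"), columns=ids, dtype=float)
        rec = screen_survival(m, clin, endpoint="os")
        assert len(rec) == 0

    def test_planted_hazard_analyte_detected(self):
        rng = np.random.default_rng(13)
        n, n_analytes = 200, 100
        vals = rng.normal(size=(n_analytes, n))
        high = vals[0] > np.median(vals[0])
        times = rng.exponential(np.exp(-np.log(3.0) * high), n)
        clin, ids = _clinical(times, np.ones(n), n)
        m = pd.DataFrame(vals, index=[f"a{i}" for i in range(n_analytes)], columns=ids)
        rec = screen_survival(m, clin, endpoint="os")
        rec0 = rec[rec["analyte"] == "a0"].iloc[0]
        assert rec0["significant"] and rec0["hr"] > 1
        assert rec["significant"].sum() <= 3  # planted plus at most FDR leakage

    def test_unsplittable_analyte_reported_not_adjusted(self):
        clin, ids = _clinical(np.arange(1.0, 9.0), np.ones(8), 8)
        m = pd.DataFrame([[1.0] * 8, [0, 1, 0, 1, 0, 1, 0, 1]], index=["flat", "ok"], columns=ids)
        rec = screen_survival(m, clin, endpoint="os")
        flat = rec[rec["analyte"] == "flat"].iloc[0]
        assert flat["status"] == STATUS_UNSPLITTABLE and np.isnan(flat["q"])
        assert rec[rec["analyte"] == "ok"].iloc[0]["status"] == STATUS_OK

    def test_no_usable_clinical_rows_raises(self):
        clin, ids = _clinical([np.nan] * 4, [np.nan] * 4, 4)
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["a"], columns=ids)
        with pytest.raises(StratumError):
            screen_survival(m, clin, endpoint="os")

    def test_null_analytes_rarely_significant(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n, n_analytes = 200, 60
            vals = rng.normal(size=(n_analytes, n))
            times = rng.exponential(1.0, n)
            events = (rng.random(n) > 0.3).astype(int)
            clin, ids = _clinical(times, events, n)
            m = pd.DataFrame(vals, index=[f"a{i}" for i in range(n_analytes)], columns=ids)
            rec = screen_survival(m, clin, endpoint="os")
            ok = rec[rec["status"] == STATUS_OK]
            fracs.append(ok["significant"].mean())
        assert np.mean(fracs) <= 0.05
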