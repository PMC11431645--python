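"""Metric suite: closed-form checks, oracle equivalence and KM/log-rank."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petfuse.errors import DegenerateInputError, ParameterError
from petfuse.evaluation import (
    c_index,
    evaluate_arm,
    km_estimate,
    log_rank,
    mape,
    pearson,
    rmsle,
)

from oracles import c_index_oracle, km_oracle


class TestRMSLE:
    def test_identity_is_zero(self):
        assert rmsle([1, 10, 100], [1, 10, 100]) == 0.0

    def test_log_e_unit(self):
        assert rmsle([0.0], [math.e - 1]) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pair(self):
        # y=[1,3], yhat=[3,1]: both terms are ln(2)^2
        assert rmsle([1.0, 3.0], [3.0, 1.0]) == pytest.approx(math.log(2), abs=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            rmsle([-1.0], [1.0])


class TestMAPE:
    def test_identity_zero(self):
        assert mape([5.0, 7.0], [5.0, 7.0]) == 0.0

    def test_double_is_100(self):
        assert mape([1.0, 50.0], [2.0, 100.0]) == pytest.approx(100.0)

    def test_hand_computed(self):
        assert mape([100.0, 200.0], [110.0, 180.0]) == pytest.approx(10.0, abs=1e-10)

    def test_zero_actual_rejected(self):
        with pytest.raises(ParameterError):
            mape([0.0], [1.0])


class TestPearson:
    def test_affine_is_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson(y, 2 * y + 5)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_negation_is_minus_one(self):
        y = np.array([1.0, 2.0, 3.0])
        r, _ = pearson(y, -y)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_half(self):
        r, _ = pearson([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert r == pytest.approx(0.5, abs=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCIndex:
    def test_perfect_ranking(self):
        t = [10.0, 20.0, 30.0]
        c, n_c = c_index(t, [1, 1, 1], [3.0, 2.0, 1.0])
        assert c == 1.0 and n_c == 3

    def test_all_ties_half(self):
        c, _ = c_index([1.0, 2.0, 3.0], [1, 1, 1], [5.0, 5.0, 5.0])
        assert c == 0.5

    def test_hand_computed_two_thirds(self):
        c, n_c = c_index([1.0, 2.0, 3.0], [1, 1, 1], [3.0, 1.0, 2.0])
        assert n_c == 3
        assert c == pytest.approx(2.0 / 3.0)

    def test_matches_oracle_random_censored(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 200))
            t = rng.exponential(100.0, size=n).round(int(rng.integers(0, 3)))
            t = np.maximum(t, 0.5)
            e = (rng.random(n) < 0.7).astype(int)
            risk = rng.normal(size=n).round(1)  # rounded to force some risk ties
            want, want_nc = c_index_oracle(t.tolist(), e.tolist(), risk.tolist())
            if want is None:
                with pytest.raises(DegenerateInputError):
                    c_index(t, e, risk)
                continue
            got, got_nc = c_index(t, e, risk)
            assert got_nc == want_nc
            assert got == pytest.approx(want, abs=1e-12)

    def test_negating_risks_flips_c(self, rng):
        n = 60
        t = rng.exponential(100.0, size=n)
        e = (rng.random(n) < 0.7).astype(int)
        risk = rng.normal(size=n)  # continuous: ties have probability zero
        c, _ = c_index(t, e, risk)
        c_neg, _ = c_index(t, e, -risk)
        assert c_neg == pytest.approx(1.0 - c, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            c_index([1.0, 2.0], [0, 0], [1.0, 2.0])

    def test_matches_lifelines_on_tie_free_data(self, rng):
        lifelines = pytest.importorskip("lifelines.utils")
        n = 100
        t = rng.exponential(100.0, size=n)
        e = (rng.random(n) < 0.6).astype(int)
        risk = rng.normal(size=n)
        c, _ = c_index(t, e, risk)
        # lifelines concordance is oriented for predicted times (low risk = long life)
        want = lifelines.concordance_index(t, -risk, e)
        assert c == pytest.approx(want, abs=1e-10)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        t = [10.0, 20.0, 30.0, 40.0]
        curve = km_estimate(t, [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat(self):
        curve = km_estimate([5.0, 6.0], [0, 0])
        assert np.all(curve.survival == 1.0)

    def test_hand_product_limit_with_ties(self):
        curve = km_estimate([1.0, 2.0, 2.0, 3.0], [1, 0, 1, 1])
        want = km_oracle([1.0, 2.0, 2.0, 3.0], [1, 0, 1, 1])
        for u, s in want.items():
            assert curve.survival_at(u) == pytest.approx(s)

    def test_monotone_and_bounded(self, rng):
        t = rng.exponential(50.0, size=80)
        e = (rng.random(80) < 0.6).astype(int)
        curve = km_estimate(t, e)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))
        assert np.all(np.diff(curve.at_risk) <= 0)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(50.0, size=60).round(0) + 1
        e = (rng.random(60) < 0.6).astype(int)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        curve = km_estimate(t, e)
        for u in np.unique(t):
            assert curve.survival_at(u) == pytest.approx(
                float(kmf.predict(u)), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        chi2, p = log_rank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        ta = np.arange(1.0, 21.0)
        tb = np.arange(100.0, 120.0)
        chi2, p = log_rank(ta, np.ones(20), tb, np.ones(20))
        assert p < 0.001

    def test_symmetric_in_group_labels(self, rng):
        ta = rng.exponential(50.0, size=30)
        tb = rng.exponential(80.0, size=25)
        ea = (rng.random(30) < 0.7).astype(int)
        eb = (rng.random(25) < 0.7).astype(int)
        c1, p1 = log_rank(ta, ea, tb, eb)
        c2, p2 = log_rank(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_matches_lifelines(self, rng):
        stats = pytest.importorskip("lifelines.statistics")
        ta = rng.exponential(50.0, size=40).round(0) + 1
        tb = rng.exponential(90.0, size=35).round(0) + 1
        ea = (rng.random(40) < 0.7).astype(int)
        eb = (rng.random(35) < 0.7).astype(int)
        res = stats.logrank_test(ta, tb, ea, eb)
        chi2, p = log_rank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)
        assert p == pytest.approx(res.p_value, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(DegenerateInputError):
            log_rank([1.0], [0], [2.0], [0])


class TestEvaluateArm:
    def test_perfect_predictions_identity_row(self):
        t = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        e = np.ones(5)
        rep = evaluate_arm(t, -np.log(t), t, e)
        assert rep.rmsle == 0.0
        assert rep.mape == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.c_index == 1.0
        assert rep.n == 5 and rep.n_events == 5 and rep.n_comparable_pairs == 10

    def test_shuffled_predictions_near_half(self, rng):
        n = 200
        t = rng.exponential(300.0, size=n)
        e = np.ones(n)
        pred = rng.permutation(t)
        rep = evaluate_arm(pred, -np.log(pred), t, e)
        assert abs(rep.c_index - 0.5) < 3 / math.sqrt(rep.n_comparable_pairs)

    def test_all_fields_finite(self, rng):
        n = 40
        t = rng.exponential(300.0, size=n)
        e = (rng.random(n) < 0.7).astype(int)
        pred = t * rng.lognormal(0, 0.5, size=n)
        rep = evaluate_arm(pred, -np.log(pred), t, e)
        assert all(np.isfinite(v) for v in rep.as_dict().values())


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(1.0, 1e4), min_size=3, max_size=40))
def test_rmsle_mape_nonnegative_and_zero_iff_equal(times):
    t = np.asarray(times)
    assert rmsle(t, t) == 0.0
    assert mape(t, t) == 0.0
    shifted = t * 1.1
    assert rmsle(t, shifted) >= 0
    assert mape(t, shifted) == pytest.approx(10.0, rel=1e-9)
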