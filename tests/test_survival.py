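import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from methet import (
    apply_horizon,
    combined_strata,
    cox_fit,
    km_rate,
    logrank_trend,
    median_split,
    segmentwise_group_test,
    welch_t,
)
from conftest import make_atoms


class TestHorizonAndKM:
    def test_administrative_censoring(self):
        t, e = apply_horizon([10, 40, 36], [True, True, True], 36)
        np.testing.assert_array_equal(t, [10, 36, 36])
        np.testing.assert_array_equal(e, [True, False, True])

    def test_no_events_rate_one(self):
        assert km_rate([40, 50, 38, 37], [0, 0, 0, 0]) == 1.0

    def test_all_events_rate_zero(self):
        assert km_rate([10, 20], [1, 1]) == 0.0

    def test_product_limit_hand_value(self):
        # one event at 12 among four subjects, three censored at 36 -> 0.75
        assert km_rate([12, 36, 36, 36], [1, 0, 0, 0]) == pytest.approx(0.75)

    def test_negative_times_error(self):
        with pytest.raises(ValueError, match="negative"):
            km_rate([-1, 5], [1, 1])


class TestLogrankTrend:
    def test_two_strata_reduces_to_ordinary_logrank(self):
        rng = np.random.default_rng(0)
        t = np.concatenate([rng.exponential(10, 40), rng.exponential(20, 40)])
        e = rng.random(80) < 0.8
        g = np.repeat([0, 1], 40)
        chi2, p = logrank_trend(t, e, g)
        ref = logrank_test(t[:40], t[40:], e[:40], e[40:])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_identical_strata_null(self):
        t = np.tile([5.0, 10.0, 15.0, 20.0], 3)
        e = np.tile([1, 0, 1, 1], 3).astype(bool)
        g = np.repeat([0, 1, 2], 4)
        chi2, p = logrank_trend(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_ordered_hazards_detected(self):
        # HRs 1, 2, 4 with n=100 per stratum: the trend should be found in
        # the vast majority of seeded replicates
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            rates = np.repeat([1.0, 2.0, 4.0], 100) / 50.0
            t = rng.exponential(1 / rates)
            e = np.ones(300, bool)
            _, p = logrank_trend(t, e, np.repeat([0, 1, 2], 100))
            hits += p < 0.05
        assert hits >= 0.9 * n_rep

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError, match="two strata"):
            logrank_trend([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_known_hazard_ratio_recovered(self):
        rng = np.random.default_rng(1)
        x = np.repeat([0, 1], 150)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.5) * x)))
        df = pd.DataFrame({"t": t, "e": 1, "x": x})
        res = cox_fit(df, "t", "e", ["x"], horizon=None)
        assert res["hr"].iloc[0] == pytest.approx(2.5, rel=0.35)
        assert res["p"].iloc[0] < 0.01

    def test_rank_deficiency_errors(self):
        df = pd.DataFrame(
            {"t": [1, 2, 3, 4.0], "e": [1, 1, 1, 1], "x": [0, 1, 0, 1],
             "x2": [0, 1, 0, 1]}
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            cox_fit(df, "t", "e", ["x", "x2"], horizon=None)

    def test_no_events_errors(self):
        df = pd.DataFrame({"t": [1.0, 2.0], "e": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, "t", "e", ["x"], horizon=None)


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = welch_t(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_separated_groups_tiny_p(self):
        t, df, p = welch_t(np.zeros(4), np.array([1, 1, 1, 1.0001]))
        assert p < 0.001

    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_equal_means_p_one(self):
        t, _, p = welch_t(np.zeros(3), np.zeros(3))
        assert (t, p) == (0.0, 1.0)

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        t, df, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestSegmentwise:
    def test_injected_shift_ranks_first(self):
        rng = np.random.default_rng(4)
        est = rng.normal(0, 0.1, (10, 50))
        est[5:, 7] += 1.0
        atoms = make_atoms([10] * 50, est)
        table = segmentwise_group_test(
            atoms, [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        )
        assert table["rank"].iloc[7] == 1
        assert table["q"].iloc[7] < 0.05

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(5)
        est = rng.normal(0, 1, (8, 100))
        atoms = make_atoms([10] * 100, est)
        table = segmentwise_group_test(
            atoms, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        )
        ordered = table.sort_values("p")
        assert (np.diff(ordered["q"].to_numpy()) >= -1e-12).all()

    def test_constant_atom_q_one(self):
        est = np.zeros((6, 3))
        est[:, 1] = [0, 0, 0, 1, 1, 1]  # one real difference
        atoms = make_atoms([10, 10, 10], est)
        table = segmentwise_group_test(
            atoms, ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        )
        assert table["q"].iloc[0] == 1.0
        assert table["q"].iloc[2] == 1.0


class TestGrouping:
    def test_median_split_assigns_median_to_high(self):
        scores = {f"p{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5])}
        split = median_split(scores)
        assert split["p2"] == "high"  # exactly at the median
        assert sum(v == "low" for v in split.values()) == 2
        assert sum(v == "high" for v in split.values()) == 3

    def test_combined_strata_cases(self):
        het = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}  # median 2.5
        cx = {"a": 10.0, "b": 10.0, "c": 10.0, "d": 60.0}
        strata = combined_strata(het, cx, 25.0).set_index("patient_id")["stratum"]
        assert strata["a"] == 0  # low het, low cx
        assert strata["c"] == 1  # high het, low cx
        assert strata["d"] == 2  # high het, high cx

    def test_missing_score_excluded(self):
        strata = combined_strata({"a": 1.0, "b": 2.0}, {"a": 10.0}, 25.0)
        assert list(strata["patient_id"]) == ["a"]
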