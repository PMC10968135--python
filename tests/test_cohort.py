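"""Normality-gated comparisons, categorical tests, Spearman, logistic."""

import numpy as np
import pandas as pd
import pytest

from aortagrowth.cohort import (compare_categorical, compare_continuous,
                                spearman, stepwise_multivariate,
                                summarize_cohort,
                                univariate_logistic_annualized)


def two_groups(a, b):
    values = np.concatenate([a, b])
    groups = np.concatenate([np.zeros(len(a), bool), np.ones(len(b), bool)])
    return values, groups


class TestCompareContinuous:
    def test_null_normal_keeps_level(self):
        """Same-distribution groups: t test chosen and p > alpha almost
        always (type-I error at the nominal 5 %)."""
        rng = np.random.default_rng(11)
        calm = 0
        t_used = 0
        for _ in range(100):
            res = compare_continuous(*two_groups(rng.normal(0, 1, 500),
                                                 rng.normal(0, 1, 500)))
            calm += res.p_value > 0.05
            t_used += res.test == "t"
        assert calm >= 94
        assert t_used >= 80

    def test_exponential_group_routes_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        picks = [compare_continuous(*two_groups(rng.exponential(1.0, 30),
                                                rng.normal(1, 1, 30))).test
                 for _ in range(50)]
        assert picks.count("mann_whitney") / len(picks) > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(4)
        res = compare_continuous(*two_groups(rng.normal(0, 1, 14),
                                             rng.normal(5, 1, 16)))
        assert res.p_value < 1e-3
        assert res.n_per_group == (14, 16)

    def test_missing_dropped_and_counted(self):
        a = np.array([1.0, 2.0, np.nan, 3.0, 2.5])
        b = np.array([2.0, 3.0, 4.0, np.nan])
        res = compare_continuous(*two_groups(a, b))
        assert res.n_per_group == (4, 3)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="x"):
            compare_continuous([np.nan, np.nan, 1, 2, 3],
                               [True, True, False, False, False],
                               variable="x")

    def test_gate_recorded(self):
        rng = np.random.default_rng(5)
        res = compare_continuous(*two_groups(rng.normal(0, 1, 20),
                                             rng.normal(0, 1, 20)))
        assert len(res.shapiro_p) == 2
        assert all(0 <= p <= 1 for p in res.shapiro_p)


class TestCompareCategorical:
    def test_small_expected_cells_use_fisher(self):
        res = compare_categorical(np.array([[10, 10], [4, 6]]))
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(0.709, abs=0.05)

    def test_balanced_table_p_one(self):
        assert compare_categorical(np.array([[5, 5], [5, 5]])).p_value == \
            pytest.approx(1.0)

    def test_perfect_association(self):
        res = compare_categorical(np.array([[20, 0], [0, 20]]))
        assert res.test == "chi_square"
        assert res.p_value < 1e-6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compare_categorical(np.zeros((2, 2), dtype=int))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical(np.array([[1, -1], [2, 3]]))


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        rx = np.array([1.0, 2.5, 2.5, 4.0])  # average ranks
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLogistic:
    def test_binary_predictor_equals_contingency_or(self):
        # a=10, b=4 (exposed), c=4, d=12 -> OR = (10*12)/(4*4) = 7.5
        x = np.array([1] * 10 + [0] * 4 + [1] * 4 + [0] * 12, dtype=float)
        y = np.array([True] * 14 + [False] * 16)
        res = univariate_logistic_annualized(x, np.ones(30), y)
        assert res.odds_ratio == pytest.approx(7.5, rel=1e-6)
        assert res.ci95[0] < res.odds_ratio < res.ci95[1]

    def test_constant_predictor_flagged(self):
        y = np.array([True] * 5 + [False] * 5)
        res = univariate_logistic_annualized(np.ones(10), np.ones(10), y)
        assert res.separated
        assert res.odds_ratio is None

    def test_perfect_separation_flagged(self):
        y = np.array([False] * 8 + [True] * 8)
        x = np.arange(16.0)  # threshold at 8 separates perfectly
        res = univariate_logistic_annualized(x, np.ones(16), y)
        assert res.separated

    def test_rescaling_invariance(self, rng):
        metric = rng.normal(200, 50, 40)
        dt = rng.uniform(1, 3, 40)
        y = rng.random(40) < 0.5
        base = univariate_logistic_annualized(metric, dt, y)
        scaled = univariate_logistic_annualized(metric, dt * 4.0, y)
        assert scaled.coef == pytest.approx(base.coef / 4.0, rel=1e-6)
        assert scaled.p_value == pytest.approx(base.p_value, abs=1e-9)

    def test_missing_rows_dropped_with_n(self, rng):
        metric = rng.normal(200, 50, 30)
        metric[:4] = np.nan
        y = np.r_[np.zeros(15, bool), np.ones(15, bool)]
        res = univariate_logistic_annualized(metric, np.ones(30), y)
        assert res.n_used == 26

    def test_profile_ci_contains_estimate(self, rng):
        metric = rng.normal(0, 1, 60)
        y = rng.random(60) < 1 / (1 + np.exp(-metric))
        res = univariate_logistic_annualized(metric, np.ones(60), y,
                                             ci="profile")
        assert res.ci95[0] < res.odds_ratio < res.ci95[1]


class TestStepwise:
    @staticmethod
    def _frame(rng, n=200, signal=True):
        x = rng.normal(size=(n, 4))
        eta = 1.5 * x[:, 0] if signal else np.zeros(n)
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        return pd.DataFrame({"growth": y, "x0": x[:, 0], "x1": x[:, 1],
                             "x2": x[:, 2], "x3": x[:, 3]})

    def test_predictive_candidate_selected(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(20):
            sel, _ = stepwise_multivariate(self._frame(rng),
                                           ["x0", "x1", "x2", "x3"])
            hits += "x0" in sel
        assert hits >= 18

    def test_pure_noise_mostly_null(self):
        rng = np.random.default_rng(22)
        empties = 0
        for _ in range(20):
            sel, _ = stepwise_multivariate(self._frame(rng, signal=False),
                                           ["x0", "x1", "x2", "x3"])
            empties += len(sel) == 0
        assert empties >= 12  # null model is the most frequent selection

    def test_single_strong_candidate_reduces_to_univariate(self):
        rng = np.random.default_rng(23)
        df = self._frame(rng)
        sel, results = stepwise_multivariate(df, ["x0"])
        assert sel == ["x0"]
        uni = univariate_logistic_annualized(df["x0"], np.ones(len(df)),
                                             df["growth"])
        assert results[0].odds_ratio == pytest.approx(uni.odds_ratio,
                                                      rel=1e-6)


class TestSummarizeCohort:
    @staticmethod
    def _cohort(rng, n=20):
        growth = np.r_[np.zeros(n // 2, bool), np.ones(n - n // 2, bool)]
        v1 = rng.uniform(100, 180, n)
        return pd.DataFrame({
            "growth": growth, "dt_years": rng.uniform(1, 3, n),
            "v1_cm3": v1,
            "v2_cm3": v1 * np.where(growth, rng.uniform(1.06, 1.2, n),
                                    rng.uniform(0.9, 1.02, n)),
            "d1_mm": rng.normal(50, 3, n), "d2_mm": rng.normal(52, 3, n),
            "P_max": rng.normal(300, 80, n)})

    def test_static_cohort_nothing_grew(self, rng):
        df = self._cohort(rng)
        df["v2_cm3"] = df["v1_cm3"]
        df["growth"] = False
        rep = summarize_cohort(df)
        assert rep["volumes"]["n_grew"] == 0
        assert "notice" in rep

    def test_perfect_diameter_volume_correlation(self, rng):
        df = self._cohort(rng)
        pct = 100.0 * (df["v2_cm3"] - df["v1_cm3"]) / df["v1_cm3"]
        df["d2_mm"] = df["d1_mm"] + pct  # diameter change == volume change
        rep = summarize_cohort(df)
        assert rep["volumes"]["spearman_diameter_vs_volume_change"]["rho"] \
            == pytest.approx(1.0)

    def test_groups_compared_with_per_metric_n(self, rng):
        df = self._cohort(rng, n=30)
        df.loc[df.index[:3], "P_max"] = np.nan
        rep = summarize_cohort(df)
        comp = rep["group_comparisons"]["P_max"]
        assert sum(comp["n_per_group"]) == 27
        assert "P_max" in rep["annualized_logistic"]
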