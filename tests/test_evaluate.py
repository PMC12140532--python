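import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristgait.errors import DataError
from wristgait.evaluate import (
    bland_altman,
    bonferroni,
    bout_means,
    compare_models,
    icc_2_1,
    subject_aggregate,
    window_metrics,
)


from _oracles import icc_2_1_oracle


class TestWindowMetrics:
    def test_hand_computed_pair(self):
        m = window_metrics([110, 90], [100, 100])
        assert m["MAE"] == 10 and m["RMSE"] == 10 and m["MAPE_pct"] == 10

    def test_perfect_prediction(self):
        m = window_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["MAE"] == 0 and m["RMSE"] == 0 and m["R2"] == 1

    def test_mean_prediction_gives_zero_r2(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0])
        m = window_metrics(np.full(4, truth.mean()), truth)
        assert m["R2"] == pytest.approx(0.0)

    def test_zero_reference_excluded_from_mape(self):
        m = window_metrics([1.0, 2.0, 1.0], [0.0, 1.0, 1.0])
        assert m["mape_n_excluded"] == 1
        assert m["MAPE_pct"] == pytest.approx(100 * (1.0 + 0.0) / 2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.integers(0, 10_000))
    def test_rmse_dominates_mae(self, truth, seed):
        rng = np.random.default_rng(seed)
        pred = np.asarray(truth) + rng.normal(size=len(truth))
        m = window_metrics(pred, np.asarray(truth))
        assert m["RMSE"] >= m["MAE"] - 1e-12


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_2_1(x, x) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc_2_1(truth + 2.0, truth) < 1.0

    def test_matches_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 12)
            truth = rng.normal(size=n)
            pred = truth + rng.normal(scale=rng.uniform(0.1, 2.0), size=n)
            assert icc_2_1(pred, truth) == pytest.approx(
                icc_2_1_oracle(pred, truth), abs=1e-8
            )

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert icc_2_1(a, b) == pytest.approx(icc_2_1(b, a), abs=1e-10)

    def test_shared_shift_invariance(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(size=10)
        pred = truth + rng.normal(scale=0.3, size=10)
        base = icc_2_1(pred, truth)
        assert icc_2_1(pred + 5, truth + 5) == pytest.approx(base, abs=1e-9)
        assert icc_2_1(pred + 5, truth) < base

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            icc_2_1([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(DataError):
            icc_2_1([1.0, 2.0], [1.0, 2.0])


class TestSubjectAggregate:
    @staticmethod
    def _frame(mapping):
        rows = []
        for sid, (pred, truth) in mapping.items():
            for p, t in zip(pred, truth):
                rows.append({"subject_id": sid, "pred": p, "truth": t})
        return pd.DataFrame(rows)

    def test_single_subject_cohort_median(self):
        df = self._frame({"s1": ([1.0, 2.0, 3.5], [1.0, 2.0, 3.0])})
        out = subject_aggregate(df)
        assert out["cohort"]["MAE"]["median"] == pytest.approx(
            out["per_subject"]["s1"]["MAE"]
        )

    def test_cohort_median_across_subjects(self):
        mapping = {
            f"s{i}": (np.array([10.0, 20.0]) + d, [10.0, 20.0])
            for i, d in enumerate([1.0, 2.0, 3.0])
        }
        out = subject_aggregate(self._frame(mapping))
        assert out["cohort"]["MAE"]["median"] == pytest.approx(2.0)

    def test_percentile_linear_interpolation(self):
        # {1,2,3,4}: 25th = 1.75, 75th = 3.25 under linear interpolation
        mapping = {
            f"s{i}": ([10.0 + d, 20.0 + d], [10.0, 20.0])
            for i, d in enumerate([1.0, 2.0, 3.0, 4.0])
        }
        out = subject_aggregate(self._frame(mapping))
        assert out["cohort"]["MAE"]["p25"] == pytest.approx(1.75)
        assert out["cohort"]["MAE"]["p75"] == pytest.approx(3.25)


class TestBlandAltman:
    def test_identity(self):
        out = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["mean_error"] == 0 and out["sd_error"] == 0
        assert out["loa_low"] == 0 and out["loa_high"] == 0

    def test_constant_bias(self):
        out = bland_altman(np.arange(5) + 5.0, np.arange(5, dtype=float))
        assert out["mean_error"] == 5 and out["sd_error"] == 0

    def test_hand_computed_sample_sd(self):
        # errors {-1, +1}: mean 0, sample SD sqrt(2), limits +/- 1.96*sqrt(2)
        out = bland_altman([0.0, 2.0], [1.0, 1.0])
        assert out["mean_error"] == 0
        assert out["sd_error"] == pytest.approx(np.sqrt(2))
        assert out["loa_high"] == pytest.approx(1.96 * np.sqrt(2))
        assert out["loa_low"] == pytest.approx(-1.96 * np.sqrt(2))

    def test_limits_cover_gaussian_errors(self):
        rng = np.random.default_rng(7)
        truth = rng.uniform(50, 150, size=10_000)
        pred = truth + rng.normal(0, 5, size=10_000)
        out = bland_altman(pred, truth)
        err = pred - truth
        cover = np.mean((err >= out["loa_low"]) & (err <= out["loa_high"]))
        assert cover >= 0.93

    def test_bout_reduction_is_unweighted_mean(self):
        df = pd.DataFrame({
            "bout_id": ["b1", "b1", "b2"],
            "pred": [1.0, 3.0, 10.0],
            "truth": [2.0, 2.0, 9.0],
        })
        bm = bout_means(df)
        assert bm.loc["b1", "pred"] == 2.0 and bm.loc["b2", "truth"] == 9.0


class TestCompareModels:
    def test_identical_columns_no_posthoc(self):
        df = pd.DataFrame({m: np.arange(8.0) for m in "abc"})
        out = compare_models(df)
        assert out["friedman"]["statistic"] == 0
        assert out["pairwise"] == []

    def test_concordant_ordering_all_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        df = pd.DataFrame({"m1": base, "m2": base + 1, "m3": base + 2})
        out = compare_models(df)
        assert out["friedman"]["p"] < 0.05
        assert len(out["pairwise"]) == 3
        assert all(p["p_raw"] < 0.05 for p in out["pairwise"])

    def test_two_models_skip_friedman(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        out = compare_models(pd.DataFrame({"a": base, "b": base + 0.5}))
        assert "friedman" not in out
        assert len(out["pairwise"]) == 1

    def test_bonferroni_definition(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.7, 3) == 1.0

    def test_shapiro_logged_per_model(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        out = compare_models(df)
        assert set(out["shapiro"]) == {"a", "b"}

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 3, 4]})
        with pytest.raises(DataError):
            compare_models(df)
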