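import numpy as np
import pandas as pd
import pytest

from wristgait.clinical import (
    build_subject_features,
    classify_disability,
    compare_feature_sets,
    cross_setting_correlation,
    stat_summary,
    summarize_subject,
    valid_day_filter,
    wrist_regularity,
)
from wristgait.errors import DataError
from wristgait.pipeline import windowed_dataset
from wristgait.simulate import CohortConfig, simulate_cohort


def _subject_table(days):
    return pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(len(days))],
         "n_valid_days": days, "disability": 0}
    )


class TestValidDayFilter:
    def test_boundary_inclusive_at_three_days(self):
        out = valid_day_filter(_subject_table([2, 3, 7]))
        assert list(out["n_valid_days"]) == [3, 7]

    def test_empty_cohort(self):
        out = valid_day_filter(_subject_table([]))
        assert out.empty


class TestStatSummary:
    def test_constant_sample(self):
        s = stat_summary([5.0] * 20, "x")
        assert s["x_mean"] == s["x_median"] == 5.0
        assert s["x_sd"] == 0 and s["x_range"] == 0
        assert all(s[f"x_d{d}"] == 5.0 for d in range(10, 100, 10))

    def test_percentile_convention_on_1_to_100(self):
        s = stat_summary(np.arange(1.0, 101.0), "x")
        assert s["x_median"] == pytest.approx(50.5)
        assert s["x_d10"] == pytest.approx(10.9)  # linear interpolation

    def test_deciles_non_decreasing(self):
        rng = np.random.default_rng(0)
        s = stat_summary(rng.normal(size=500), "x")
        deciles = [s[f"x_d{d}"] for d in range(10, 100, 10)]
        assert all(a <= b for a, b in zip(deciles, deciles[1:]))

    def test_gaussian_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(1)
        s = stat_summary(rng.standard_normal(10_000), "x")
        assert abs(s["x_kurtosis"]) < 0.2

    def test_summarize_requires_windows(self):
        with pytest.raises(DataError):
            summarize_subject(pd.DataFrame(), pd.DataFrame())


class TestWristRegularity:
    def test_periodic_wrist_signal_scores_high(self):
        t = np.arange(300) / 30.0
        mag = 1.0 + 0.3 * np.sin(2 * np.pi * 1.0 * t)
        assert wrist_regularity(mag, 30.0) > 0.95

    def test_noise_scores_low(self):
        rng = np.random.default_rng(2)
        vals = [wrist_regularity(1 + 0.1 * rng.standard_normal(300), 30.0)
                for _ in range(10)]
        assert np.nanmean(vals) < 0.5


@pytest.fixture(scope="module")
def clinical_cohort():
    """Multi-day cohort with the valid-day filter exercisable."""
    # prevalence 0.5 keeps every stratified outer fold two-class at n = 40
    cfg = CohortConfig(wear_days_range=(3, 4), bouts_per_day_mean=3.0,
                       label_flip_prob=0.0, disability_prevalence=0.5)
    cohort = simulate_cohort(40, cfg, seed=13)
    X, meta = windowed_dataset(cohort)
    return cohort, X, meta


@pytest.fixture(scope="module")
def feature_sets(clinical_cohort):
    cohort, X, meta = clinical_cohort
    daily, pa, sup = build_subject_features(cohort, meta, X)
    tab = cohort.subject_table().set_index("subject_id")
    y = tab.loc[daily.index, "disability"]
    return daily, pa, sup, y


class TestFeatureBuilding:
    def test_one_row_per_retained_subject(self, clinical_cohort, feature_sets):
        cohort, _, _ = clinical_cohort
        daily, pa, sup, _ = feature_sets
        retained = valid_day_filter(cohort.subject_table())
        assert set(daily.index) <= set(retained["subject_id"])
        assert list(daily.index) == list(pa.index) == list(sup.index)

    def test_feature_order_invariant_to_subject_order(self, clinical_cohort):
        cohort, X, meta = clinical_cohort
        daily1, _, _ = build_subject_features(cohort, meta, X)
        shuffled = meta.sample(frac=1.0, random_state=0)
        daily2, _, _ = build_subject_features(cohort, shuffled, X)
        daily2 = daily2.loc[daily1.index, daily1.columns]
        pd.testing.assert_frame_equal(daily1, daily2)

    def test_decile_columns_non_decreasing(self, feature_sets):
        daily, _, _, _ = feature_sets
        cols = [f"win_speed_cms_d{d}" for d in range(10, 100, 10)]
        vals = daily[cols].to_numpy()
        assert (np.diff(vals, axis=1) >= -1e-9).all()


class TestClassification:
    def test_latent_driven_disability_is_learnable(self, feature_sets):
        # no label noise: disability is the latent-threshold indicator and
        # the gait features carry the latent almost noiselessly
        daily, _, _, y = feature_sets
        res = classify_disability(daily, y, seed=0)
        assert res["mean_auc"] >= 0.9

    def test_same_seed_identical_folds(self, feature_sets):
        daily, _, _, y = feature_sets
        r1 = classify_disability(daily, y, seed=3)
        r2 = classify_disability(daily, y, seed=3)
        assert r1["fold_aucs"] == r2["fold_aucs"]

    def test_outer_folds_partition_subjects(self, feature_sets):
        daily, _, _, y = feature_sets
        res = classify_disability(daily, y, seed=1)
        seen = []
        for tr_ids, te_ids in zip(res["fold_train_subjects"],
                                  res["fold_test_subjects"]):
            assert not set(tr_ids) & set(te_ids)  # no leakage within a fold
            seen.extend(te_ids)
        assert sorted(seen) == sorted(daily.index)  # each subject tested once

    def test_too_few_subjects_rejected(self):
        F = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(DataError):
            classify_disability(F, np.repeat([0, 1], 5))


class TestFeatureSetComparison:
    def test_identical_columns_not_significant(self):
        col = np.linspace(0.6, 0.9, 10)
        out = compare_feature_sets(pd.DataFrame({"a": col, "b": col, "c": col}))
        assert out["friedman"]["statistic"] == 0

    def test_dominant_column_detected(self):
        rng = np.random.default_rng(0)
        base = 0.7 + 0.02 * rng.normal(size=10)
        df = pd.DataFrame({"a": base, "b": base + 0.005, "c": base + 0.15})
        out = compare_feature_sets(df)
        assert out["friedman"]["p"] < 0.05
        assert len(out["pairwise"]) == 3  # Bonferroni factor = 3 pairs

    def test_mismatched_folds_rejected(self):
        df = pd.DataFrame({"a": [0.7, 0.8, np.nan], "b": [0.6, 0.7, 0.8]})
        with pytest.raises(DataError):
            compare_feature_sets(df)


class TestCrossSettingCorrelation:
    def test_diagonal_is_one_and_monotone_copy_correlates(self, feature_sets):
        daily, _, sup, _ = feature_sets
        corr = cross_setting_correlation(sup[["short_speed_cms"]],
                                         daily[["win_speed_cms_mean"]])
        assert np.allclose(np.diag(corr), 1.0)

    def test_monotone_transform_preserves_rank_correlation(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame({"x": rng.normal(size=30)})
        b = pd.DataFrame({"y": np.exp(a["x"])})
        corr = cross_setting_correlation(a, b)
        assert corr.loc["x", "y"] == pytest.approx(1.0)

    def test_independent_features_uncorrelated(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame({"x": rng.normal(size=500)})
        b = pd.DataFrame({"y": rng.normal(size=500)})
        corr = cross_setting_correlation(a, b)
        assert abs(corr.loc["x", "y"]) < 0.1

    def test_too_few_paired_subjects_rejected(self):
        a = pd.DataFrame({"x": [1.0, 2, 3]})
        b = pd.DataFrame({"y": [1.0, 2, 3]})
        with pytest.raises(DataError):
            cross_setting_correlation(a, b)
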