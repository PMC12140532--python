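"""Clinical-utility stage: multi-day feature summarization and nested-CV
classification of mobility disability.

Per subject, each gait metric (speed, stride length, cadence, regularity)
is summarized by {mean, median, SD, kurtosis, skewness, range, deciles
10th-90th} at the 10-s window level and at the walking-bout level. Physical
activity (PA) features apply the same statistic set to the acceleration
magnitude, per day over the whole recording and over walking segments, then
averaged across days. Subjects with fewer than three valid wear days are
excluded.

Classification uses a gradient-boosted-tree classifier under nested
cross-validation (5-fold inner randomized search, 10-fold outer, stratified
and subject-wise — one feature row per subject, so subject leakage is
structurally impossible) with the outer-fold AUC as the primary metric.
Feature-set comparison treats outer-fold AUCs as paired samples and
delegates to the Friedman / Wilcoxon / Bonferroni machinery.

Conventions pinned here: sample SD (ddof=1), excess kurtosis (normal = 0),
percentiles by linear interpolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from .baseline import biomech_features
from .errors import DataError
from .evaluate import compare_models
from .labels import stride_regularity
from .simulate import SimulatedCohort

STAT_DECILES = list(range(10, 100, 10))

DEFAULT_SEARCH_SPACE = {
    "n_estimators": [25, 50, 100],
    "max_depth": [2, 3, 4],
    "learning_rate": [0.05, 0.1, 0.3],
    "subsample": [0.7, 1.0],
    "min_child_weight": [1, 3],
}


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def stat_summary(values, prefix: str) -> dict[str, float]:
    """The pinned statistic set over a 1-D sample."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DataError("no finite values to summarize")
    out = {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        f"{prefix}_kurtosis": float(stats.kurtosis(x, fisher=True)) if x.size > 3 else 0.0,
        f"{prefix}_skewness": float(stats.skew(x)) if x.size > 2 else 0.0,
        f"{prefix}_range": float(np.ptp(x)),
    }
    for d in STAT_DECILES:
        out[f"{prefix}_d{d}"] = float(np.percentile(x, d))
    return out


def valid_day_filter(subject_table: pd.DataFrame, min_days: int = 3) -> pd.DataFrame:
    """Retain subjects with >= ``min_days`` valid wear days (boundary inclusive)."""
    if subject_table.empty:
        return subject_table.copy()
    keep = subject_table["n_valid_days"] >= min_days
    return subject_table.loc[keep].copy()


def summarize_subject(
    window_metrics_df: pd.DataFrame,
    bout_metrics_df: pd.DataFrame,
    pa_daily: pd.DataFrame | None = None,
) -> dict[str, float]:
    """One feature row for a subject.

    ``window_metrics_df`` / ``bout_metrics_df``: one row per window / bout
    with a column per gait metric. ``pa_daily``: one row per day with
    magnitude-summary columns; daily values are averaged across days.
    """
    if window_metrics_df.empty:
        raise DataError("subject has no valid windows")
    row: dict[str, float] = {}
    for col in window_metrics_df.columns:
        row.update(stat_summary(window_metrics_df[col], f"win_{col}"))
    for col in bout_metrics_df.columns:
        row.update(stat_summary(bout_metrics_df[col], f"bout_{col}"))
    if pa_daily is not None and not pa_daily.empty:
        for col in pa_daily.columns:
            row[f"pa_{col}"] = float(pa_daily[col].mean())
    return row


def wrist_regularity(mag: np.ndarray, fs: float) -> float:
    """Regularity from wrist data alone: the lag comes from the estimated
    cadence (no stride annotations exist in free-living wrist data)."""
    feats = biomech_features(np.column_stack([mag, np.zeros_like(mag),
                                              np.zeros_like(mag)]), fs)
    stride_s = 120.0 / feats.cadence_est_spm
    reg, valid = stride_regularity(mag, stride_s, fs)
    return reg if valid else float("nan")


# ---------------------------------------------------------------------------
# cohort-level feature building
# ---------------------------------------------------------------------------

def build_subject_features(
    cohort: SimulatedCohort,
    window_table: pd.DataFrame,
    window_tensor: np.ndarray | None = None,
    min_days: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build the three per-subject feature sets from a simulated cohort.

    Returns (daily_gait, pa, supervised) DataFrames indexed by subject_id,
    restricted to subjects passing the valid-day filter.

    * daily_gait: window- and bout-level summaries of the four gait metrics
      from the free-living window table (wrist-derived regularity included).
    * pa: daily acceleration-magnitude summaries over whole recordings and
      walking segments, averaged across days.
    * supervised: short-walk per-test means of speed/stride/cadence plus
      lower-back regularity, emulating standardized in-clinic gait tests.
    """
    retained = valid_day_filter(cohort.subject_table(), min_days)
    keep = set(retained["subject_id"])
    gait_rows, pa_rows, sup_rows = {}, {}, {}
    metrics = ["speed_cms", "stride_len_cm", "cadence_spm", "regularity"]
    for spec in cohort.subjects:
        sid = spec.subject_id
        if sid not in keep:
            continue
        sub_win = window_table[window_table["subject_id"] == sid]
        if sub_win.empty:
            continue
        win_df = sub_win[metrics + ["bout_id"]].copy()
        if window_tensor is not None:
            # free-living regularity comes from the wrist signal itself,
            # with the autocorrelation lag taken from estimated cadence
            win_df["regularity"] = [
                wrist_regularity(
                    np.linalg.norm(window_tensor[i], axis=1), cohort.config.fs
                )
                for i in sub_win.index
            ]
        bout_df = win_df.groupby("bout_id")[metrics].mean()
        gait_rows[sid] = summarize_subject(win_df[metrics], bout_df)

        days = cohort.days_for(sid)
        pa_daily = []
        for d in days:
            mag = np.linalg.norm(d.wrist.samples, axis=1)
            rowd = stat_summary(mag, "day_all")
            walk_mask = np.zeros(mag.size, dtype=bool)
            for b in d.bouts:
                i0 = int(round(b.start_s * d.wrist.fs))
                i1 = int(round(b.end_s * d.wrist.fs))
                walk_mask[i0:i1] = True
            if walk_mask.any():
                rowd.update(stat_summary(mag[walk_mask], "day_walk"))
            rowd["n_bouts"] = len(d.bouts)
            pa_daily.append(rowd)
        pa_rows[sid] = pd.DataFrame(pa_daily).mean().to_dict()

        sup_rows[sid] = _supervised_features(spec, cohort)

    daily_gait = pd.DataFrame.from_dict(gait_rows, orient="index")
    pa = pd.DataFrame.from_dict(pa_rows, orient="index")
    supervised = pd.DataFrame.from_dict(sup_rows, orient="index")
    for df in (daily_gait, pa, supervised):
        df.index.name = "subject_id"
    return daily_gait, pa, supervised


def _supervised_features(spec, cohort: SimulatedCohort) -> dict[str, float]:
    """Emulated standardized walking tests: two short bouts per subject,
    summarized by per-test means of the stride-level annotations."""
    from .simulate import GaitParams, simulate_bout

    cfg = cohort.config
    rng = np.random.default_rng(abs(hash(spec.subject_id)) % (2**31))
    out: dict[str, float] = {}
    for test, dur in (("short", 4.0), ("long", 10.0)):
        speed = float(np.clip(rng.normal(spec.speed_mu_cms, cfg.bout_speed_sd), 40, 170))
        cadence = float(np.clip(rng.normal(spec.cadence_mu_spm, cfg.bout_cadence_sd), 60, 160))
        params = GaitParams.from_speed_cadence(
            speed,
            cadence,
            swing_amp_g=cfg.swing_amp_for_speed(speed),
            impact_amp_g=cfg.impact_amp_g,
            jitter_sd_s=spec.jitter_sd_s,
            noise_sd_g=cfg.noise_sd_g,
        )
        _, lumbar, bout = simulate_bout(params, dur, cfg.fs, rng=rng,
                                        subject_id=spec.subject_id)
        durs = [s.duration_s for s in bout.strides]
        out[f"{test}_speed_cms"] = float(np.mean([s.speed_cms for s in bout.strides]))
        out[f"{test}_stride_len_cm"] = float(np.mean([s.length_cm for s in bout.strides]))
        out[f"{test}_cadence_spm"] = 120.0 / float(np.mean(durs))
        reg, valid = stride_regularity(lumbar.vertical, float(np.mean(durs)), cfg.fs)
        out[f"{test}_regularity"] = reg if valid else float("nan")
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_disability(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int = 0,
    outer_folds: int = 10,
    inner_folds: int = 5,
    n_iter: int = 5,
    search_space: dict | None = None,
) -> dict:
    """Nested-CV gradient-boosted-tree classification of disability.

    One row per subject (subject-wise partitioning); the inner randomized
    search selects hyperparameters by AUC, the outer loop yields
    ``outer_folds`` held-out AUCs. Returns fold AUCs, mean +/- SD, and a
    mean ROC curve sampled on a fixed FPR grid.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] < 30:
        raise DataError("need >= 30 subjects for nested cross-validation")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    space = search_space or DEFAULT_SEARCH_SPACE
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fpr_grid = np.linspace(0, 1, 101)
    fold_aucs, tprs, fold_params = [], [], []
    fold_train_subjects, fold_test_subjects = [], []
    ids = np.asarray(features.index)
    for k, (tr, te) in enumerate(outer.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise DataError("single-class outer fold; stratification failed")
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                random_state=seed + k)
        search = RandomizedSearchCV(
            XGBClassifier(
                eval_metric="logloss",
                tree_method="hist",
                random_state=seed,
                n_jobs=1,
            ),
            space,
            n_iter=n_iter,
            scoring="roc_auc",
            cv=inner,
            random_state=seed + k,
            n_jobs=1,
        )
        search.fit(X[tr], y[tr])
        proba = search.best_estimator_.predict_proba(X[te])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[te], proba)))
        fpr, tpr, _ = roc_curve(y[te], proba)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
        fold_params.append(search.best_params_)
        fold_train_subjects.append([str(s) for s in ids[tr]])
        fold_test_subjects.append([str(s) for s in ids[te]])
    return {
        "fold_train_subjects": fold_train_subjects,
        "fold_test_subjects": fold_test_subjects,
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "sd_auc": float(np.std(fold_aucs, ddof=1)),
        "roc_points": {
            "fpr": fpr_grid.tolist(),
            "tpr": np.mean(tprs, axis=0).tolist(),
        },
        "best_params_per_fold": fold_params,
    }


def compare_feature_sets(fold_auc_matrix: pd.DataFrame) -> dict:
    """Friedman + post hoc Wilcoxon over paired outer-fold AUC columns."""
    if fold_auc_matrix.isna().any().any():
        raise DataError("mismatched fold counts across feature sets")
    return compare_models(fold_auc_matrix)


def cross_setting_correlation(
    supervised_features: pd.DataFrame, daily_features: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation matrix between (and within) the two settings."""
    joined = supervised_features.join(daily_features, how="inner",
                                      lsuffix="_sup", rsuffix="_daily")
    if len(joined) < 5:
        raise DataError("need >= 5 paired subjects")
    return joined.corr(method="spearman")
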