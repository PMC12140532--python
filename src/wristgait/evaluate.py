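"""Agreement, error and model-comparison statistics.

Window-level errors (MAE, RMSE, MAPE, R^2) are aggregated per subject; the
cohort summary is the median and [25th, 75th] percentile across subjects
(linear interpolation between closest ranks). Method agreement uses
ICC(2,1) — two-way random effects, absolute agreement, single measurement,
which penalizes systematic bias — and Bland-Altman limits of agreement
(mean error +/- 1.96 sample SD) on bout-level means.

Multi-model comparison is nonparametric throughout: a Shapiro-Wilk check is
computed and logged per model column (informational), an omnibus Friedman
test gates post hoc pairwise two-sided Wilcoxon signed-rank tests, and
p-values are Bonferroni-adjusted (p_adj = min(1, p x number of tests)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import DataError


# ---------------------------------------------------------------------------
# window-level metrics
# ---------------------------------------------------------------------------

def window_metrics(pred, truth) -> dict:
    """MAE, RMSE, MAPE (%) and R^2 for paired prediction/reference vectors.

    MAPE excludes pairs whose reference is 0 (count reported as
    ``mape_n_excluded``; MAPE is NaN when no pair remains).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise DataError("pred and truth must be equal-length with n >= 2")
    err = pred - truth
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    nz = truth != 0
    mape = (
        float(100.0 * np.mean(np.abs(err[nz] / truth[nz]))) if nz.any() else float("nan")
    )
    sst = float(np.sum((truth - truth.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return {
        "MAE": mae,
        "RMSE": rmse,
        "MAPE_pct": mape,
        "R2": r2,
        "mape_n_excluded": int((~nz).sum()),
    }


def icc_2_1(pred, truth) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size != truth.size or pred.size < 3:
        raise DataError("ICC needs >= 3 paired observations")
    if np.ptp(truth) == 0 and np.ptp(pred) == 0:
        raise DataError("ICC undefined for constant measurements")
    n = pred.size
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["truth", "pred"], n),
            "score": np.concatenate([truth, pred]),
        }
    )
    res = pg.intraclass_corr(
        data=df, targets="target", raters="rater", ratings="score"
    )
    # the two-way random / absolute agreement / single-rater row is labelled
    # "ICC2" or "ICC(A,1)" depending on the pingouin release
    row = res["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(res.loc[row, "ICC"].iloc[0])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def percentile(values, q) -> float:
    """Linear-interpolation percentile (the pinned convention)."""
    return float(np.percentile(np.asarray(values, dtype=float), q))


def subject_aggregate(results: pd.DataFrame, min_windows: int = 2) -> dict:
    """Per-subject metrics and their cohort summary.

    ``results`` has columns subject_id, pred, truth (one row per window).
    Per-subject error metrics are computed over that subject's windows
    (ICC additionally requires >= 3 windows); the cohort summary is
    median and [25th, 75th] percentiles across subjects.
    """
    if results.empty:
        raise DataError("no results to aggregate")
    per_subject: dict[str, dict] = {}
    for sid, grp in results.groupby("subject_id", sort=True):
        if len(grp) < min_windows:
            continue
        m = window_metrics(grp["pred"].to_numpy(), grp["truth"].to_numpy())
        try:
            m["ICC"] = icc_2_1(grp["pred"].to_numpy(), grp["truth"].to_numpy())
        except DataError:
            m["ICC"] = float("nan")
        per_subject[str(sid)] = m
    if not per_subject:
        raise DataError("no subject had enough windows")
    cohort = {}
    for metric in ("MAE", "RMSE", "MAPE_pct", "R2", "ICC"):
        vals = np.array([m[metric] for m in per_subject.values()], dtype=float)
        vals = vals[np.isfinite(vals)]
        cohort[metric] = {
            "median": percentile(vals, 50) if vals.size else float("nan"),
            "p25": percentile(vals, 25) if vals.size else float("nan"),
            "p75": percentile(vals, 75) if vals.size else float("nan"),
        }
    return {"per_subject": per_subject, "cohort": cohort}


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(pred_bout, truth_bout) -> dict:
    """Limits of agreement on per-bout values: mean error +/- 1.96 sample SD."""
    pred = np.asarray(pred_bout, dtype=float)
    truth = np.asarray(truth_bout, dtype=float)
    if pred.size != truth.size or pred.size < 2:
        raise DataError("Bland-Altman needs >= 2 paired bouts")
    err = pred - truth
    mean_error = float(np.mean(err))
    sd_error = float(np.std(err, ddof=1))
    return {
        "mean_error": mean_error,
        "sd_error": sd_error,
        "loa_low": mean_error - 1.96 * sd_error,
        "loa_high": mean_error + 1.96 * sd_error,
        "n_bouts": int(pred.size),
    }


def bout_means(window_values: pd.DataFrame) -> pd.DataFrame:
    """Reduce window-level pred/truth to per-bout unweighted means.

    ``window_values`` has columns bout_id, pred, truth.
    """
    return window_values.groupby("bout_id", sort=True)[["pred", "truth"]].mean()


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null distribution is used for n <= 25 pairs, the normal approximation
    with continuity correction above.
    """
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             method=method)
    except ValueError:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             method="approx")
    return float(res.pvalue)


def bonferroni(p: float, n_tests: int) -> float:
    return float(min(1.0, p * n_tests))


def compare_models(metric_matrix: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Friedman omnibus + post hoc Wilcoxon with Bonferroni correction.

    ``metric_matrix`` is subjects x models (one column per model). With
    three or more models, pairwise tests run only when the Friedman test is
    significant at ``alpha``; with exactly two models, the Wilcoxon test
    runs directly. Shapiro-Wilk normality checks are logged per column; the
    nonparametric path is always taken.
    """
    df = metric_matrix.dropna()
    n, k = df.shape
    if k < 2:
        raise DataError("need >= 2 models to compare")
    if n < 5:
        raise DataError("need >= 5 subjects for the signed-rank comparison")

    shapiro = {}
    for col in df.columns:
        vals = df[col].to_numpy()
        if np.ptp(vals) == 0:
            shapiro[str(col)] = {"W": float("nan"), "p": float("nan")}
        else:
            w, p = stats.shapiro(vals)
            shapiro[str(col)] = {"W": float(w), "p": float(p)}

    out: dict = {"n_subjects": int(n), "n_models": int(k), "shapiro": shapiro}
    cols = list(df.columns)
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]

    run_posthoc = True
    if k >= 3:
        if df.nunique(axis=1).eq(1).all():
            friedman_stat, friedman_p = 0.0, 1.0
        else:
            friedman_stat, friedman_p = stats.friedmanchisquare(
                *[df[c].to_numpy() for c in cols]
            )
        out["friedman"] = {"statistic": float(friedman_stat),
                           "p": float(friedman_p)}
        run_posthoc = friedman_p < alpha

    out["pairwise"] = []
    if run_posthoc:
        n_tests = len(pairs)
        for a, b in pairs:
            p_raw = _wilcoxon(df[a].to_numpy(), df[b].to_numpy())
            out["pairwise"].append(
                {
                    "model_a": str(a),
                    "model_b": str(b),
                    "p_raw": p_raw,
                    "p_bonferroni": bonferroni(p_raw, n_tests),
                }
            )
    return out
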