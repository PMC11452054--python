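"""Psychometric evaluation of measurement-level gait features.

Three analyses mirror how clinimetric properties of gait measures are
established:

* test-retest reliability: ICC(2,1) — two-way random effects, absolute
  agreement, single measurement — with its 95% confidence interval, the
  standard error of measurement SEM = sd_pooled * sqrt(1 - ICC) and the
  minimal detectable change MDC = 1.96 * sqrt(2) * SEM;
* group differences: independent two-sample t-test (pooled variance by
  default) and Hedges' g with the small-sample bias correction;
* responsiveness: an individual changed on a feature when the admission to
  discharge difference exceeds that feature's MDC (strictly), counted only
  for features with good-to-excellent reliability by default.

ICC categories use the conventional cut points 0.5 / 0.75 / 0.9
(poor / moderate / good / excellent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

MDC_FACTOR = 1.96 * math.sqrt(2.0)  # ~2.77186


@dataclass
class ReliabilityResult:
    feature: str
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    mdc: float
    n_pairs: int
    category: str


@dataclass
class GroupComparison:
    feature: str
    mean_a: float
    sd_a: float
    min_a: float
    max_a: float
    n_a: int
    mean_b: float
    sd_b: float
    min_b: float
    max_b: float
    n_b: int
    t_stat: float
    p_value: float
    hedges_g: float


def icc_category(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_2_1(test: Sequence[float], retest: Sequence[float],
            alpha: float = 0.05) -> Tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``test`` and ``retest`` are paired by subject (equal length n >= 3, no
    missing values). Returns ``(icc, ci_low, ci_high)`` with the 95% CI from
    the F-distribution method. Raises when the score matrix is constant
    (both variance components zero), where the ICC is undefined.
    """
    x = np.column_stack([np.asarray(test, dtype=float),
                         np.asarray(retest, dtype=float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing values must be dropped upstream")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0 and msc == 0):
        raise ValueError("ICC undefined: no variance in the score matrix")
    icc = (msr - mse) / denom

    # 95% CI, F-distribution method (two-way random, absolute agreement)
    if mse == 0 and msc == 0:
        return float(icc), 1.0, 1.0
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return float(icc), 1.0, 1.0
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    ci_low = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    ci_high = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(ci_low), float(ci_high)


def sem_mdc(test: Sequence[float], retest: Sequence[float], icc: float,
            estimator: str = "pooled_sd") -> Tuple[float, float]:
    """SEM and MDC of a test-retest pair.

    Default SEM = sd_pooled * sqrt(1 - ICC) with sd_pooled the SD of all 2n
    scores; ``estimator="ms_error"`` uses sqrt(MS_E) of the two-way ANOVA
    instead. MDC = 1.96 * sqrt(2) * SEM always.
    """
    x = np.column_stack([np.asarray(test, dtype=float),
                         np.asarray(retest, dtype=float)])
    if estimator == "pooled_sd":
        sem = float(x.std(ddof=1) * math.sqrt(max(1.0 - icc, 0.0)))
    elif estimator == "ms_error":
        n, k = x.shape
        grand = x.mean()
        ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
        ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
        ss_err = np.sum((x - grand) ** 2) - ss_rows - ss_cols
        sem = float(math.sqrt(max(ss_err / ((n - 1) * (k - 1)), 0.0)))
    else:
        raise ValueError("estimator must be 'pooled_sd' or 'ms_error'")
    return sem, MDC_FACTOR * sem


def reliability(test: Sequence[float], retest: Sequence[float], feature: str = "",
                sem_estimator: str = "pooled_sd") -> ReliabilityResult:
    """ICC(2,1) + CI + SEM + MDC + category for one feature."""
    icc, lo, hi = icc_2_1(test, retest)
    sem, mdc = sem_mdc(test, retest, icc, sem_estimator)
    return ReliabilityResult(feature=feature, icc=icc, ci_low=lo, ci_high=hi,
                             sem=sem, mdc=mdc, n_pairs=len(test),
                             category=icc_category(icc))


def independent_t(a: Sequence[float], b: Sequence[float],
                  welch: bool = False) -> Tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    res = stats.ttest_ind(np.asarray(a, dtype=float), np.asarray(b, dtype=float),
                          equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def hedges_g(mean_a: float, sd_a: float, n_a: int,
             mean_b: float, sd_b: float, n_b: int,
             corrected: bool = True) -> float:
    """Hedges' g (standardized mean difference, small-sample corrected).

    g = J * (mean_b - mean_a) / s_p with pooled SD
    s_p^2 = ((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2) and
    J = 1 - 3 / (4 (n_a + n_b) - 9). Invariant under a common affine
    rescaling of both groups.
    """
    df = n_a + n_b - 2
    if df <= 0:
        raise ValueError("need at least 3 observations in total")
    sp = math.sqrt(((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / df)
    if sp == 0:
        raise ValueError("pooled SD is zero")
    d = (mean_b - mean_a) / sp
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0) if corrected else 1.0
    return j * d


def compare_groups(a: Sequence[float], b: Sequence[float], feature: str = "",
                   welch: bool = False) -> GroupComparison:
    """Summary statistics, t-test and Hedges' g for two independent groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = independent_t(a, b, welch)
    g = hedges_g(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
    return GroupComparison(feature=feature,
                           mean_a=a.mean(), sd_a=a.std(ddof=1), min_a=a.min(),
                           max_a=a.max(), n_a=a.size,
                           mean_b=b.mean(), sd_b=b.std(ddof=1), min_b=b.min(),
                           max_b=b.max(), n_b=b.size,
                           t_stat=t, p_value=p, hedges_g=g)


def classify_change(delta: float, mdc: float) -> str:
    """"increased" / "decreased" when |delta| strictly exceeds the MDC, else "none"."""
    if delta > mdc:
        return "increased"
    if delta < -mdc:
        return "decreased"
    return "none"


def responsiveness(t0: pd.DataFrame, tend: pd.DataFrame,
                   reliability_results: Iterable[ReliabilityResult],
                   features: Sequence[str] = None,
                   speed_feature: str = "gait_speed_mps",
                   reliable_only: bool = True) -> Dict:
    """Per-individual change classification against feature MDCs.

    ``t0`` / ``tend`` are per-subject feature tables indexed by
    ``subject_id``. Features without good-to-excellent reliability are
    excluded when ``reliable_only``; the speed feature is always evaluated.
    Subjects missing in either session are dropped (logged in the result).
    Returns a dict with the per-subject long table, per-feature counts and
    the changed-any / changed-speed / changed-both summary.
    """
    rel = {r.feature: r for r in reliability_results}
    if features is None:
        features = [f for f in rel if f != speed_feature]
    if reliable_only:
        features = [f for f in features
                    if f in rel and rel[f].category in ("good", "excellent")]
    eval_features = list(features) + ([speed_feature] if speed_feature in rel else [])

    t0i = t0.set_index("subject_id") if "subject_id" in t0.columns else t0
    tei = tend.set_index("subject_id") if "subject_id" in tend.columns else tend
    common = t0i.index.intersection(tei.index)
    excluded = sorted(set(t0i.index).symmetric_difference(set(tei.index)))

    rows = []
    for sid in common:
        for f in eval_features:
            delta = float(tei.loc[sid, f]) - float(t0i.loc[sid, f])
            rows.append(dict(subject_id=sid, feature=f, delta=delta,
                             mdc=rel[f].mdc, changed=classify_change(delta, rel[f].mdc)))
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no paired subjects to evaluate")

    per_feature = (table.groupby("feature")["changed"]
                   .value_counts().unstack(fill_value=0)
                   .reindex(columns=["increased", "decreased", "none"], fill_value=0))
    latent_tbl = table[table["feature"] != speed_feature]
    changed_latent = set(latent_tbl.loc[latent_tbl["changed"] != "none", "subject_id"])
    speed_tbl = table[table["feature"] == speed_feature]
    changed_speed = set(speed_tbl.loc[speed_tbl["changed"] != "none", "subject_id"])
    return {
        "table": table,
        "per_feature_counts": per_feature,
        "n_subjects": int(len(common)),
        "excluded_subjects": excluded,
        "changed_any_latent": sorted(changed_latent),
        "changed_gait_speed": sorted(changed_speed),
        "changed_both": sorted(changed_latent & changed_speed),
        "n_changed_any": int(len(changed_latent | changed_speed)),
    }


def reliability_table(test_df: pd.DataFrame, retest_df: pd.DataFrame,
                      features: Sequence[str],
                      sem_estimator: str = "pooled_sd") -> Tuple[pd.DataFrame, List[ReliabilityResult]]:
    """Reliability of several features from subject-paired test/retest tables."""
    t0 = test_df.set_index("subject_id")
    t1 = retest_df.set_index("subject_id")
    common = t0.index.intersection(t1.index)
    results = []
    for f in features:
        a = t0.loc[common, f].to_numpy(dtype=float)
        b = t1.loc[common, f].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        results.append(reliability(a[ok], b[ok], feature=f, sem_estimator=sem_estimator))
    df = pd.DataFrame([r.__dict__ for r in results])
    return df, results
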