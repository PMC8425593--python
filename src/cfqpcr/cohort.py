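"""Cohort-level pre/post-treatment statistics and per-patient trajectories.

The central clinical question is whether each circulating transcript *falls*
after thyroid surgery or radioiodine ablation. Expression is on the 60−Ct
scale, patients are their own controls (paired pre vs post), and the cohort
is summarized per target as: number and proportion of patients with a fall,
median (IQR) pre and post, the percent fall of the cohort medians, and a
Wilcoxon signed-rank p-value.

Because patients are sampled at several post-treatment timepoints (24 h,
1 week, 1 month, 6 months), a pairing *policy* chooses the post value:
``any_fall`` (default) takes the minimum across post timepoints — a patient
counts as falling if any visit shows it — while ``earliest_post`` and
``latest_post`` pin a single visit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away

log = logging.getLogger(__name__)

PAIRING_POLICIES = ("earliest_post", "latest_post", "any_fall")


class WilcoxonResult(NamedTuple):
    p_value: float
    method: str  # "exact" | "approx" | "degenerate"
    n_used: int  # pairs remaining after dropping zero differences


@dataclass(frozen=True)
class DetectionSummary:
    target: str
    n_detected_patients: int
    n_patients: int
    rate: int  # integer percent


def pair_pre_post(expr: pd.DataFrame, meta: pd.DataFrame,
                  policy: str = "any_fall") -> pd.DataFrame:
    """One (pre, post) expression pair per patient × target.

    The pre value is the patient's latest pre-treatment sample (closest to
    treatment); the post value follows ``policy``. Patients lacking a pre or
    a post sample are skipped with a warning. Only the treatment cohort is
    paired.
    """
    if policy not in PAIRING_POLICIES:
        raise ValueError(f"unknown pairing policy {policy!r}")
    m = meta[meta["cohort_group"] == "treatment"]
    joined = expr.merge(
        m[["sample_id", "patient_id", "day", "phase", "timepoint_label"]],
        on="sample_id", how="inner")

    rows = []
    for (patient, target), grp in joined.groupby(["patient_id", "target"], sort=False):
        pre = grp[grp["phase"] == "pre"]
        post = grp[grp["phase"] == "post"]
        if pre.empty or post.empty:
            which = "pre" if pre.empty else "post"
            warnings.warn(f"patient {patient} has no {which} sample; skipped")
            continue
        pre_row = pre.loc[pre["day"].idxmax()]
        if policy == "earliest_post":
            post_row = post.loc[post["day"].idxmin()]
        elif policy == "latest_post":
            post_row = post.loc[post["day"].idxmax()]
        else:  # any_fall: the minimum expression across post visits, earliest on ties
            post = post.sort_values("day", kind="stable")
            post_row = post.loc[post["expression"].idxmin()]
        rows.append((patient, target, float(pre_row["expression"]),
                     float(post_row["expression"]), post_row["timepoint_label"]))
    pairs = pd.DataFrame(rows, columns=["patient_id", "target", "expression_pre",
                                        "expression_post", "post_timepoint_used"])
    pairs.attrs["policy"] = policy
    return pairs


def fall_flag(expression_pre: float, expression_post: float) -> bool:
    """A fall is a strict decrease; an unchanged level is not a fall."""
    return expression_post < expression_pre


def fall_proportion(n_fall: int, n_total: int) -> int:
    """Integer percent of the cohort with a fall, ties rounded away from zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_fall <= n_total:
        raise ValueError("n_fall must lie in [0, n_total]")
    return round_half_away(100.0 * n_fall / n_total)


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation, inclusive rule)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty set")
    return (float(np.median(arr)),
            float(np.percentile(arr, 25)),
            float(np.percentile(arr, 75)))


def percent_fall_of_medians(median_pre: float, median_post: float) -> Optional[int]:
    """Signed integer percent change of the cohort median, fall negative.

    Undefined (None) when the pre-treatment median is 0 — a transcript never
    detected before treatment has no baseline to fall from.
    """
    if median_pre < 0 or median_post < 0:
        raise ValueError("medians must be nonnegative")
    if median_pre == 0:
        return None
    return -round_half_away(100.0 * (median_pre - median_post) / median_pre)


def wilcoxon_signed_rank(pre, post, alternative: str = "two_sided") -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on pre vs post expression.

    Zero differences are dropped (Wilcoxon's convention). The exact null
    distribution is used for n ≤ 25 without tied |differences|; otherwise the
    normal approximation with tie correction. ``greater_fall`` tests the
    one-sided alternative that expression fell (pre > post).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise ValueError("pre and post must be equal-length, nonempty")
    d = pre - post
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return WilcoxonResult(1.0, "degenerate", 0)
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    alt = {"two_sided": "two-sided", "greater_fall": "greater"}[alternative]
    res = stats.wilcoxon(d, zero_method="wilcox", alternative=alt, method=method)
    return WilcoxonResult(float(res.pvalue), method, int(d.size))


def detection_rate(expr: pd.DataFrame, meta: pd.DataFrame, target: str,
                   cohort_group: str = "treatment") -> DetectionSummary:
    """Fraction of patients with the transcript detected at ≥1 timepoint.

    Detected means expression > 0, i.e. a verified product called before the
    cycle ceiling.
    """
    m = meta[meta["cohort_group"] == cohort_group]
    joined = expr[expr["target"] == target].merge(
        m[["sample_id", "patient_id"]], on="sample_id", how="inner")
    per_patient = joined.groupby("patient_id")["expression"].max()
    n_patients = int(per_patient.size)
    if n_patients == 0:
        raise ValueError(f"no patients with wells for target {target!r}")
    n_det = int((per_patient > 0).sum())
    return DetectionSummary(target, n_det, n_patients,
                            round_half_away(100.0 * n_det / n_patients))


def summarize_targets(expr: pd.DataFrame, meta: pd.DataFrame, panel: pd.DataFrame,
                      policy: str = "any_fall",
                      alternative: str = "two_sided") -> pd.DataFrame:
    """Per-target cohort summary over the thyroid-specific panel.

    Healthy-volunteer levels are summarized as the arithmetic mean of
    expression across healthy-control samples (NaN when the cohort has
    none). Deterministic in, and invariant to, input row order.
    """
    thyroid = [t for t in panel.loc[panel["target_class"] == "thyroid_specific", "target"]]
    pairs = pair_pre_post(expr, meta, policy=policy)
    healthy_samples = set(meta.loc[meta["cohort_group"] == "healthy_control", "sample_id"])

    rows = []
    for target in thyroid:
        tp = pairs[pairs["target"] == target].sort_values("patient_id", kind="stable")
        healthy_vals = expr.loc[
            (expr["target"] == target) & expr["sample_id"].isin(healthy_samples), "expression"]
        healthy_mean = float(healthy_vals.mean()) if len(healthy_vals) else np.nan
        if tp.empty:
            rows.append({"target": target, "n_fall": 0, "n_total": 0,
                         "fall_proportion": np.nan, "healthy_mean": healthy_mean,
                         "median_pre": np.nan, "q1_pre": np.nan, "q3_pre": np.nan,
                         "median_post": np.nan, "q1_post": np.nan, "q3_post": np.nan,
                         "percent_fall_of_medians": np.nan, "p_value": np.nan})
            continue
        falls = [fall_flag(a, b) for a, b in zip(tp["expression_pre"], tp["expression_post"])]
        n_fall, n_total = int(sum(falls)), len(falls)
        med_pre, q1_pre, q3_pre = median_iqr(tp["expression_pre"])
        med_post, q1_post, q3_post = median_iqr(tp["expression_post"])
        pct = percent_fall_of_medians(med_pre, med_post)
        p = wilcoxon_signed_rank(tp["expression_pre"], tp["expression_post"],
                                 alternative=alternative).p_value
        rows.append({"target": target, "n_fall": n_fall, "n_total": n_total,
                     "fall_proportion": fall_proportion(n_fall, n_total),
                     "healthy_mean": healthy_mean,
                     "median_pre": med_pre, "q1_pre": q1_pre, "q3_pre": q3_pre,
                     "median_post": med_post, "q1_post": q1_post, "q3_post": q3_post,
                     "percent_fall_of_medians": np.nan if pct is None else pct,
                     "p_value": p})
    out = pd.DataFrame(rows)
    out.attrs["policy"] = policy
    out.attrs["alternative"] = alternative
    return out


def trajectory(expr: pd.DataFrame, meta: pd.DataFrame, patient_id: str,
               target: str) -> pd.DataFrame:
    """Time-ordered expression series for one patient and target, with the
    clinical annotations (TSH stimulation, serum TG, TG Ab, imaging) merged
    for plotting or reporting. Missing annotations stay missing — absence of
    a TG measurement is not a TG of 0.
    """
    if patient_id not in set(meta["patient_id"]):
        raise KeyError(f"unknown patient {patient_id!r}")
    m = meta[meta["patient_id"] == patient_id]
    cols = ["sample_id", "day", "phase", "timepoint_label",
            "tsh_stimulated", "serum_tg", "tg_ab", "structural_disease"]
    cols = [c for c in cols if c in m.columns]
    joined = expr[expr["target"] == target].merge(m[cols], on="sample_id", how="inner")
    return joined.sort_values("day", kind="stable").reset_index(drop=True)
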