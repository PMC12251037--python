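"""Responder stratification and normality-gated paired statistics.

Patients with hyperhomocysteinemia are split by the observed direction of
their plasma homocysteine (HCY) change under folic-acid supplementation:
*responders* (HCY fell) versus *non-responders* (HCY unchanged or rose).
Paired before/after biomarker comparisons are gated on a Shapiro-Wilk
normality test of the paired differences: normal differences get Student's
paired t-test, non-normal ones the Wilcoxon matched-pairs signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

#: biomarker columns expected in a cohort table, as (before, after) pairs
BIOMARKERS = {
    "hcy": ("hcy_before", "hcy_after"),
    "folate": ("folate_before", "folate_after"),
    "cfdna": ("cfdna_before", "cfdna_after"),
}


@dataclass(frozen=True)
class TestResult:
    """Outcome of a normality-gated paired comparison."""

    statistic: float
    p_value: float
    test_used: str  # "paired_t" | "wilcoxon_signed_rank" | "degenerate"
    n_pairs: int
    normality_p: float
    degenerate: bool = False


def classify_response(hcy_before: float, hcy_after: float) -> str:
    """Label one patient from the sign of the HCY change.

    Strictly decreased HCY -> responder; unchanged or increased ->
    non-responder (ties count as non-response).
    """
    if hcy_before is None or hcy_after is None:
        raise ValueError("both HCY timepoints are required for classification")
    b, a = float(hcy_before), float(hcy_after)
    if not (np.isfinite(b) and np.isfinite(a)):
        raise ValueError("both HCY timepoints must be finite")
    if b <= 0 or a <= 0:
        raise ValueError("HCY concentrations must be positive")
    return RESPONDER if a < b else NON_RESPONDER


def relative_change(before: float, after: float) -> float:
    """Signed percent change, 100 * (after - before) / before."""
    before = float(before)
    if before == 0:
        raise ValueError("relative change is undefined for a zero baseline")
    return 100.0 * (float(after) - before) / before


def label_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Label every fully observed patient in a cohort table.

    Patients missing either HCY timepoint are excluded (and reported with a
    warning). Returns columns ``patient_id``, ``label``,
    ``hcy_relative_change_percent``.
    """
    required = {"patient_id", "hcy_before", "hcy_after"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    complete = cohort.dropna(subset=["hcy_before", "hcy_after"])
    n_dropped = len(cohort) - len(complete)
    if n_dropped:
        warnings.warn(f"{n_dropped} patient(s) excluded: missing HCY timepoint")
    rows = [
        {
            "patient_id": r.patient_id,
            "label": classify_response(r.hcy_before, r.hcy_after),
            "hcy_relative_change_percent": relative_change(r.hcy_before, r.hcy_after),
        }
        for r in complete.itertuples()
    ]
    return pd.DataFrame(rows, columns=["patient_id", "label", "hcy_relative_change_percent"])


def paired_compare(before, after, alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk-gated paired comparison of two matched vectors.

    Pairs with a missing value are dropped (pairwise deletion). The gate is
    applied to the paired differences: if their Shapiro-Wilk p >= ``alpha``
    a paired t-test is used, otherwise the Wilcoxon signed-rank test.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after vectors must have equal length")
    keep = np.isfinite(before) & np.isfinite(after)
    before, after = before[keep], after[keep]
    n = len(before)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    diffs = after - before
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; comparison is degenerate")
        return TestResult(0.0, 1.0, "degenerate", n, float("nan"), degenerate=True)
    normality_p = float(stats.shapiro(diffs).pvalue)
    if normality_p >= alpha:
        res = stats.ttest_rel(after, before)
        return TestResult(float(res.statistic), float(res.pvalue), "paired_t", n, normality_p)
    res = stats.wilcoxon(after, before)
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank", n, normality_p)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a zero-variance vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return float(r), float(p)


def summarize_group(values) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and n of a value list."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n == 0:
        raise ValueError("cannot summarize an empty group")
    sd = float(np.std(values, ddof=1)) if n > 1 else float("nan")
    return float(np.mean(values)), sd, n


def biomarker_report(
    cohort: pd.DataFrame, labels: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-group and overall before/after summaries for every biomarker.

    One row per (group, biomarker): mean +/- SD at each timepoint, the gated
    paired test, and the mean per-patient relative change.
    """
    merged = cohort.merge(labels[["patient_id", "label"]], on="patient_id", how="left")
    rows = []
    groups = [("all", merged)] + [
        (lab, merged[merged["label"] == lab]) for lab in (RESPONDER, NON_RESPONDER)
    ]
    for group_name, sub in groups:
        for marker, (bcol, acol) in BIOMARKERS.items():
            if bcol not in sub.columns or acol not in sub.columns:
                continue
            pair = sub.dropna(subset=[bcol, acol])
            if len(pair) < 3:
                warnings.warn(f"stratum {group_name}/{marker} skipped: <3 complete pairs")
                continue
            mb, sb, n = summarize_group(pair[bcol])
            ma, sa, _ = summarize_group(pair[acol])
            test = paired_compare(pair[bcol], pair[acol], alpha=alpha)
            rel = [relative_change(b, a) for b, a in zip(pair[bcol], pair[acol])]
            rows.append(
                {
                    "group": group_name,
                    "biomarker": marker,
                    "n": n,
                    "before_mean": mb,
                    "before_sd": sb,
                    "after_mean": ma,
                    "after_sd": sa,
                    "mean_relative_change_percent": float(np.mean(rel)),
                    "test_used": test.test_used,
                    "statistic": test.statistic,
                    "p_value": test.p_value,
                    "normality_p": test.normality_p,
                }
            )
    return pd.DataFrame(rows)
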