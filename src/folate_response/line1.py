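"""LINE-1 bisulfite-pyrosequencing methylation summaries.

LINE-1 retrotransposon methylation proxies global genome methylation. Each
sample fraction (plasma cfDNA, granulocytes, mononuclear cells) is measured
at three CpG positions per timepoint; the per-sample summary is their
arithmetic mean. Group-level change is the mean of per-patient relative
changes, 100 * (post - baseline) / baseline, computed on the averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stratification as strat

FRACTIONS = ("cfDNA", "granulocyte", "mononuclear")
TIMEPOINTS = ("baseline", "post")
CPG_COLS = ("cpg1", "cpg2", "cpg3")


def average_line1(cpg1: float, cpg2: float, cpg3: float) -> float:
    """Mean methylation percent of the three LINE-1 CpG positions.

    Full precision is returned; outputs are rounded to one decimal only at
    the reporting layer.
    """
    vals = [float(cpg1), float(cpg2), float(cpg3)]
    for v in vals:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"methylation percent out of [0, 100]: {v}")
    return sum(vals) / 3.0


def validate_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Check schema/ranges of a LINE-1 table and attach the ``average`` column."""
    required = {"patient_id", "fraction", "timepoint", *CPG_COLS}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"LINE-1 table is missing columns: {sorted(missing)}")
    bad_frac = set(profiles["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise ValueError(f"unknown fractions: {sorted(bad_frac)}")
    bad_tp = set(profiles["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    out = profiles.copy()
    out["average"] = [
        average_line1(r.cpg1, r.cpg2, r.cpg3) for r in out.itertuples()
    ]
    return out


def table1(profiles: pd.DataFrame, alpha: float = 0.05, holm: bool = False) -> pd.DataFrame:
    """Fraction x CpG x timepoint summary table (mean +/- SD, paired p).

    Mirrors the usual presentation of pyrosequencing panels: one row per
    fraction and CpG position (plus the three-CpG average), with one-decimal
    means/SDs and a significance mark on the paired comparison. The three
    per-CpG tests are unadjusted by default; ``holm`` applies a Holm
    correction across the CpG positions within each fraction (the average
    row stays unadjusted).
    """
    prof = validate_profiles(profiles)
    rows = []
    for fraction in FRACTIONS:
        sub = prof[prof["fraction"] == fraction]
        if sub.empty:
            continue
        wide = sub.pivot(index="patient_id", columns="timepoint",
                         values=list(CPG_COLS) + ["average"])
        for site in list(CPG_COLS) + ["average"]:
            pair = wide[site].dropna()
            if len(pair) < 3:
                warnings.warn(f"{fraction}/{site}: <3 complete pairs, skipped")
                continue
            test = strat.paired_compare(pair["baseline"], pair["post"], alpha=alpha)
            mb, sb, n = strat.summarize_group(pair["baseline"])
            ma, sa, _ = strat.summarize_group(pair["post"])
            rows.append(
                {
                    "fraction": fraction,
                    "site": site,
                    "n": n,
                    "baseline_mean": round(mb, 1),
                    "baseline_sd": round(sb, 1),
                    "post_mean": round(ma, 1),
                    "post_sd": round(sa, 1),
                    "p_value": test.p_value,
                    "significant": test.p_value < alpha,
                }
            )
    table = pd.DataFrame(rows)
    if holm and not table.empty:
        from statsmodels.stats.multitest import multipletests

        for fraction in table["fraction"].unique():
            mask = (table["fraction"] == fraction) & (table["site"] != "average")
            if mask.sum() >= 2:
                reject, adj, _, _ = multipletests(
                    table.loc[mask, "p_value"], alpha=alpha, method="holm"
                )
                table.loc[mask, "p_value"] = adj
                table.loc[mask, "significant"] = reject
    return table


def _fraction_analysis(wide: pd.DataFrame, alpha: float) -> dict:
    test = strat.paired_compare(wide["baseline"], wide["post"], alpha=alpha)
    rel = [
        strat.relative_change(b, a)
        for b, a in zip(wide["baseline"], wide["post"])
    ]
    return {
        "n": len(wide),
        "baseline_mean": float(np.mean(wide["baseline"])),
        "post_mean": float(np.mean(wide["post"])),
        "mean_relative_change_percent": float(np.mean(rel)),
        "test_used": test.test_used,
        "p_value": test.p_value,
    }


def line1_change_analysis(
    profiles: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Baseline-vs-post analysis of the three-CpG average, per fraction.

    For each fraction: the gated paired test and the mean per-patient
    relative change, overall and (when ``labels`` is given) within each
    response group. When ``cohort`` is given, the post-supplementation HCY
    level is correlated (Pearson) with the post LINE-1 average per group.
    Strata with fewer than three complete pairs are skipped with a warning.
    """
    prof = validate_profiles(profiles)
    label_map = (
        dict(zip(labels["patient_id"], labels["label"])) if labels is not None else {}
    )
    hcy_map = (
        dict(zip(cohort["patient_id"], cohort["hcy_after"])) if cohort is not None else {}
    )
    report: dict = {}
    for fraction in FRACTIONS:
        sub = prof[prof["fraction"] == fraction]
        if sub.empty:
            continue
        wide = sub.pivot(index="patient_id", columns="timepoint", values="average").dropna()
        if len(wide) < 3:
            warnings.warn(f"fraction {fraction}: <3 complete pairs, skipped")
            continue
        entry = _fraction_analysis(wide, alpha)
        entry["per_group"] = {}
        if label_map:
            for group in (strat.RESPONDER, strat.NON_RESPONDER):
                ids = [i for i in wide.index if label_map.get(i) == group]
                gw = wide.loc[ids]
                if len(gw) < 3:
                    warnings.warn(f"{fraction}/{group}: <3 complete pairs, skipped")
                    continue
                gentry = _fraction_analysis(gw, alpha)
                if hcy_map:
                    hcy = [hcy_map.get(i, np.nan) for i in gw.index]
                    r, p = strat.correlate(hcy, gw["post"], method="pearson")
                    gentry["hcy_correlation_r"] = r
                    gentry["hcy_correlation_p"] = p
                entry["per_group"][group] = gentry
        report[fraction] = entry
    return report


def relative_change_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-patient relative change of the three-CpG average, per fraction."""
    prof = validate_profiles(profiles)
    rows = []
    for fraction in FRACTIONS:
        sub = prof[prof["fraction"] == fraction]
        if sub.empty:
            continue
        wide = sub.pivot(index="patient_id", columns="timepoint", values="average").dropna()
        for pid, row in wide.iterrows():
            rows.append(
                {
                    "patient_id": pid,
                    "fraction": fraction,
                    "relative_change_percent": strat.relative_change(
                        row["baseline"], row["post"]
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "fraction", "relative_change_percent"])
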