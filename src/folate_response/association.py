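"""Per-gene mutation burden vs. biological-age-change association.

For each panel gene, the number of variant records per patient is
correlated (Spearman rank order) with the patient's biological-age delta,
and a univariate least-squares line ``delta = intercept + slope * count``
is fitted. Raw p-values are reported by default; a Benjamini-Hochberg
column is attached whenever two or more genes are tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import VariantRecord


def burden_matrix(
    variants: list[VariantRecord],
    panel_genes: list[str] | None = None,
    patients: list[str] | None = None,
) -> pd.DataFrame:
    """Patient-by-gene mutation-count matrix, zero-filled.

    ``panel_genes`` / ``patients`` extend the index beyond what the variant
    list mentions, so genes or patients without any variant appear as zero
    rows/columns.
    """
    genes = set(panel_genes or [])
    pids = set(patients or [])
    for v in variants:
        genes.add(v.gene)
        pids.add(v.patient_id)
    matrix = pd.DataFrame(0, index=sorted(pids), columns=sorted(genes), dtype=int)
    for v in variants:
        matrix.loc[v.patient_id, v.gene] += 1
    return matrix


def associate(
    burden: pd.DataFrame,
    deltas: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    group: str | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene Spearman correlation and OLS line of delta on burden.

    ``deltas`` needs columns ``patient_id`` and ``delta``. When ``group``
    is given the analysis is restricted to patients with that label. Genes
    with constant burden in the analyzed patients are skipped and flagged.
    Returns one row per gene: spearman_r, p_value, adjusted_p (NaN unless
    requested and >= 2 genes), intercept, slope, n, skipped.
    """
    delta_map = dict(zip(deltas["patient_id"], deltas["delta"]))
    pids = [p for p in burden.index if p in delta_map]
    if group is not None:
        if labels is None:
            raise ValueError("labels are required when a group filter is requested")
        wanted = set(labels.loc[labels["label"] == group, "patient_id"])
        pids = [p for p in pids if p in wanted]
    if len(pids) < 3:
        raise ValueError("need at least 3 patients with both burden and delta")
    y = np.array([delta_map[p] for p in pids], dtype=float)
    rows = []
    for gene in burden.columns:
        x = burden.loc[pids, gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append(
                {
                    "gene": gene,
                    "spearman_r": np.nan,
                    "p_value": np.nan,
                    "adjusted_p": np.nan,
                    "intercept": np.nan,
                    "slope": np.nan,
                    "n": len(pids),
                    "skipped": True,
                }
            )
            continue
        r, p = stats.spearmanr(x, y)
        fit = stats.linregress(x, y)
        rows.append(
            {
                "gene": gene,
                "spearman_r": float(r),
                "p_value": float(p),
                "adjusted_p": np.nan,
                "intercept": float(fit.intercept),
                "slope": float(fit.slope),
                "n": len(pids),
                "skipped": False,
            }
        )
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    if adjust and tested.sum() >= 2:
        out.loc[tested, "adjusted_p"] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return out
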