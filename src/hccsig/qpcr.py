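"""Delta-delta-Ct relative quantification and array/qPCR concordance.

Replicate Ct values are averaged on the Ct scale per (gene, sample); the
group delta-Ct is the mean over samples of Ct_target - Ct_reference, the
delta-delta-Ct is delta_case - delta_control, and the relative fold change
is efficiency^(-ddct) with the classical efficiency of 2 (one doubling per
cycle), so log2(fold) = -ddct exactly.
"""

from __future__ import annotations

import json
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CtTable, ValidationError


def delta_delta_ct(
    ct: CtTable,
    case_group: str = "CASE",
    control_group: str = "CONTROL",
    efficiency: float = 2.0,
    per_subject: bool = False,
) -> pd.DataFrame:
    """Per-gene ddCt results relative to the table's reference gene.

    With ``per_subject`` the delta-Ct is formed within each sample before
    group averaging (identical for complete tables, robust to unbalanced
    reference measurements otherwise); the default averages group means,
    the standard bulk formulation.
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    t = ct.table
    ref = ct.reference_gene
    # replicate Cts averaged per (gene, sample)
    per_sample = t.groupby(["gene", "sample", "group"], as_index=False)["ct"].mean()
    ref_ct = per_sample[per_sample["gene"] == ref].set_index("sample")["ct"]
    rows = []
    for gene, sub in per_sample.groupby("gene", sort=True):
        deltas = {}
        ok = True
        for group in (case_group, control_group):
            g = sub[sub["group"] == group]
            if g.empty:
                ok = False
                break
            d = g["ct"].to_numpy() - ref_ct.loc[g["sample"]].to_numpy()
            deltas[group] = float(np.mean(d))
        if not ok:
            continue  # gene absent in one group: skipped
        ddct = deltas[case_group] - deltas[control_group]
        log2fc = -ddct * math.log2(efficiency)
        rep_sd = float(
            t[t["gene"] == gene].groupby("sample")["ct"].std(ddof=1).mean()
        )
        rows.append(
            {
                "gene": gene,
                "delta_ct_case": deltas[case_group],
                "delta_ct_control": deltas[control_group],
                "ddct": ddct,
                "fold": efficiency ** (-ddct),
                "log2fc": log2fc,
                "replicate_sd": rep_sd,
            }
        )
    cols = [
        "gene",
        "delta_ct_case",
        "delta_ct_control",
        "ddct",
        "fold",
        "log2fc",
        "replicate_sd",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def concordance(
    array_log2fc: Sequence[float], qpcr_log2fc: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between platform fold changes, with its p-value.

    Requires >= 3 finite pairs; zero variance in either vector is
    untestable (NaN, NaN).
    """
    x = np.asarray(array_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("fold-change vectors differ in length")
    if x.size < 3:
        raise ValidationError("concordance needs >= 3 paired genes")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("fold-change vectors must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ddct_tsv(result: pd.DataFrame) -> str:
    return result.reset_index().to_csv(sep="\t", index=False)


def concordance_json(r: float, p: float, n: int) -> str:
    return json.dumps({"pearson_r": r, "p_value": p, "n_genes": n}, indent=2, sort_keys=True)
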