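"""Independent brute-force oracles the tests check the implementation against.

Deliberately naive: explicit loops, exact integer combinatorics, all-pairs
scans.  Nothing here may import the code paths under test.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats


def brute_two_way_anova(y, treatment, age):
    """Cell-means two-factor ANOVA for one gene, textbook formulas."""
    treatment = np.asarray(treatment)
    age = np.asarray(age)
    y = np.asarray(y, dtype=float)
    t_levels = sorted(set(treatment))
    a_levels = sorted(set(age))
    gm = y.mean()
    ss_t = sum((treatment == t).sum() * (y[treatment == t].mean() - gm) ** 2 for t in t_levels)
    ss_a = sum((age == a).sum() * (y[age == a].mean() - gm) ** 2 for a in a_levels)
    ss_int = 0.0
    ss_res = 0.0
    n_cells = 0
    for t in t_levels:
        for a in a_levels:
            cell = y[(treatment == t) & (age == a)]
            if cell.size == 0:
                continue
            n_cells += 1
            m = cell.mean()
            ss_int += cell.size * (m - y[treatment == t].mean() - y[age == a].mean() + gm) ** 2
            ss_res += ((cell - m) ** 2).sum()
    df_t, df_a = len(t_levels) - 1, len(a_levels) - 1
    df_int = (n_cells - 1) - df_t - df_a
    df_res = y.size - n_cells
    ms_res = ss_res / df_res
    out = {}
    for term, ss, df in (("treatment", ss_t, df_t), ("age", ss_a, df_a), ("interaction", ss_int, df_int)):
        f = (ss / df) / ms_res
        out[f"F_{term}"] = f
        out[f"p_{term}"] = stats.f.sf(f, df, df_res)
    return out


def enum_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact integer enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    hi = min(K, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1)) / total


def partial_sum_binom_upper_tail(k: int, n: int, rate: float) -> float:
    """P(X >= k) as the explicit partial sum sum_{i>=k} C(n,i) rate^i (1-rate)^(n-i)."""
    return sum(comb(n, i) * rate**i * (1 - rate) ** (n - i) for i in range(k, n + 1))


def brute_interval_overlaps(gene_loci, cna_regions):
    """All-pairs half-open overlap scan: gene -> sorted overlapping regions."""
    hits = {}
    for gene, locus in gene_loci.items():
        hits[gene] = sorted(
            r
            for r in cna_regions
            if r.chrom == locus.chrom and locus.start < r.end and r.start < locus.end
        )
    return hits
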