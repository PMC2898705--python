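"""Gene-set over-representation statistics over user-supplied GMT collections.

Two right-tailed tests per set: the Fisher exact test (identical to the
upper-tail hypergeometric kernel used for cross-dataset overlaps) and the
binomial test at background rate K/N — the classical category-enrichment
pair.  Raw p-values are reported (no correction by default).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .conservation import hypergeom_overlap
from .io_formats import ValidationError


def fisher_right(k: int, n: int, K: int, N: int) -> float:
    """Right-tailed Fisher exact p: P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValidationError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def binom_right(k: int, n: int, rate: float) -> float:
    """Right-tailed binomial p: sum_{i>=k} C(n,i) rate^i (1-rate)^(n-i)."""
    if not 0 <= rate <= 1:
        raise ValidationError("rate must lie in [0, 1]")
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = float(stats.binom.sf(k - 1, n, rate))
    return min(max(p, 0.0), 1.0)


def enrich(
    gene_list: Iterable[str],
    gmt_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every gene set against the list within the universe.

    Rows: name, k (list hits), n (list size in universe), K (set size in
    universe), N, p_fisher, p_binom, significant (p_fisher < alpha).  Sets
    with no member in the universe get k = K = 0 and p = 1.  Sorted by
    p_fisher ascending, ties by name.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    genes = set(gene_list)
    stray = genes - uni
    if stray:
        raise ValidationError(f"gene_list not within universe: {sorted(stray)[:5]}")
    N = len(uni)
    n = len(genes)
    rows = []
    for name in sorted(gmt_sets):
        members = set(gmt_sets[name]) & uni
        K = len(members)
        k = len(members & genes)
        if K == 0:
            p_f, p_b = 1.0, 1.0
        else:
            p_f = fisher_right(k, n, K, N)
            p_b = binom_right(k, n, K / N)
        rows.append(
            {
                "name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_fisher": p_f,
                "p_binom": p_b,
                "significant": p_f < alpha,
            }
        )
    out = pd.DataFrame(
        rows, columns=["name", "k", "n", "K", "N", "p_fisher", "p_binom", "significant"]
    )
    return out.sort_values(["p_fisher", "name"], kind="mergesort").reset_index(drop=True)


def enrichment_tsv(table: pd.DataFrame) -> str:
    return table.to_csv(sep="\t", index=False)


# definitional identity with the list-overlap kernel, re-exported for callers
__all__ = ["fisher_right", "binom_right", "enrich", "enrichment_tsv", "hypergeom_overlap"]
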