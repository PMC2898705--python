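"""Ortholog mapping and cross-dataset conservation of the signature.

Each human cohort contributes a case/control DE call (unpaired t-test);
the signature's overlap with each call is scored by the upper-tail
hypergeometric probability within an explicit universe (ortholog-mapped
genes measured in that dataset) and Bonferroni-adjusted over the number of
datasets.  Conservation tiers: conserved-in-any (DE in >= 1 dataset) and
shared-by-all (DE in every dataset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import fold_change, unpaired_t
from .io_formats import CohortExperiment, OrthologTable, ValidationError


@dataclass
class OverlapTest:
    """Counts and significance of a two-list overlap within a universe."""

    N: int  # universe size
    K: int  # list A within universe
    n: int  # list B within universe
    k: int  # overlap
    p_raw: float
    p_adj: float = float("nan")
    m: int = 1  # tests adjusted over

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ConservationResult:
    conserved_any: set[str]
    shared_all: set[str]
    overlap_tests: dict[str, OverlapTest]
    unmapped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "conserved_any": sorted(self.conserved_any),
            "shared_all": sorted(self.shared_all),
            "overlap_tests": {d: t.to_dict() for d, t in sorted(self.overlap_tests.items())},
            "unmapped": sorted(self.unmapped),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def map_orthologs(
    signature: pd.DataFrame, ortho: OrthologTable
) -> tuple[pd.DataFrame, list[str]]:
    """Translate a signature to the target (human) namespace.

    Two source genes hitting the same symbol merge into one entry with
    pooled provenance (a direction disagreement flags the merged entry).
    Unmapped source genes are returned, not silently dropped.
    """
    unmapped = sorted(g for g in signature["gene"] if g not in ortho.mapping)
    mapped = signature[signature["gene"].isin(ortho.mapping)].copy()
    if mapped.empty:
        return (
            pd.DataFrame(columns=["gene", "direction", "sources", "conflicted", "source_genes"]),
            unmapped,
        )
    mapped["symbol"] = mapped["gene"].map(ortho.mapping)
    rows = []
    for symbol, sub in mapped.groupby("symbol", sort=True):
        directions = list(dict.fromkeys(sub["direction"]))
        sources = sorted({s for joined in sub["sources"] for s in joined.split(";")})
        rows.append(
            {
                "gene": symbol,
                "direction": directions[0],
                "sources": ";".join(sources),
                "conflicted": bool(sub["conflicted"].any() or len(directions) > 1),
                "source_genes": ";".join(sorted(sub["gene"])),
            }
        )
    return pd.DataFrame(rows), unmapped


def dataset_de_call(
    cohort: CohortExperiment,
    alpha: float = 0.001,
    fc_min: float | None = None,
    equal_var: bool = False,
    floor: float = 1.0,
) -> set[str]:
    """Case-vs-control DE genes of one cohort: t-test p < alpha (strict).

    The fold-change gate is off by default; pass ``fc_min`` to require
    |FC| > fc_min as well.
    """
    if alpha < 0 or alpha > 1:
        raise ValidationError("alpha must lie in [0, 1]")
    cases = cohort.group_samples("CASE")
    controls = cohort.group_samples("CONTROL")
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError(f"cohort {cohort.name!r}: need >= 2 cases and controls")
    log_m = np.log2(cohort.intensities.clip(lower=floor))
    tt = unpaired_t(log_m, cases, controls, equal_var=equal_var)
    keep = (tt["p"] < alpha) & tt["p"].notna()
    if fc_min is not None:
        fc = fold_change(cohort.intensities, cases, controls)
        keep &= fc["abs_fc"] > fc_min
    return set(tt.index[keep])


def dataset_de_directions(
    cohort: CohortExperiment,
    alpha: float = 0.001,
    fc_min: float | None = None,
    equal_var: bool = False,
    floor: float = 1.0,
) -> pd.Series:
    """Direction (UP/DOWN in cases) of each DE-called gene of a cohort."""
    called = dataset_de_call(cohort, alpha, fc_min, equal_var, floor)
    fc = fold_change(
        cohort.intensities,
        cohort.group_samples("CASE"),
        cohort.group_samples("CONTROL"),
    )
    genes = sorted(called)
    return pd.Series(fc.loc[genes, "direction"].to_numpy(), index=genes, dtype=object)


def hypergeom_overlap(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> OverlapTest:
    """Upper-tail hypergeometric probability of the observed overlap.

    p_raw = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size,
    K = |A|, n = |B| and k = |A ∩ B| (all restricted to the universe).
    """
    uni = set(universe)
    a = set(list_a)
    b = set(list_b)
    for name, s in (("list_a", a), ("list_b", b)):
        stray = s - uni
        if stray:
            raise ValidationError(f"{name} not within universe: {sorted(stray)[:5]}")
    N, K, n, k = len(uni), len(a), len(b), len(a & b)
    # survival function at k-1 gives P(X >= k); exact in scipy's hypergeom
    p_raw = float(stats.hypergeom.sf(k - 1, N, K, n)) if N else 1.0
    return OverlapTest(N=N, K=K, n=n, k=k, p_raw=min(max(p_raw, 0.0), 1.0))


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """p_adj_i = min(1, m * p_i) with m = number of tests."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


def conservation_tiers(
    mapped_signature: Iterable[str],
    de_sets: dict[str, set[str]],
    universes: dict[str, set[str]],
) -> ConservationResult:
    """Conserved-in-any / shared-by-all tiers plus per-dataset overlap tests.

    ``universes[d]`` is the universe for dataset d (ortholog-mapped genes
    measured on that platform); the signature and DE set are restricted to
    it before testing.  Bonferroni m = number of datasets.
    """
    if not de_sets:
        raise ValidationError("need >= 1 dataset DE set")
    if set(de_sets) != set(universes):
        raise ValidationError("de_sets and universes must cover the same datasets")
    sig = set(mapped_signature)
    tests: dict[str, OverlapTest] = {}
    for d in sorted(de_sets):
        uni = universes[d]
        if not uni:
            raise ValidationError(f"dataset {d!r}: empty universe")
        tests[d] = hypergeom_overlap(sig & uni, de_sets[d] & uni, uni)
    adj = bonferroni([tests[d].p_raw for d in sorted(tests)])
    for d, p_adj in zip(sorted(tests), adj):
        tests[d].p_adj = float(p_adj)
        tests[d].m = len(tests)
    any_de: set[str] = set().union(*de_sets.values())
    all_de = set.intersection(*de_sets.values())
    return ConservationResult(
        conserved_any=sig & any_de,
        shared_all=sig & all_de,
        overlap_tests=tests,
    )


def tiers_tsv(result: ConservationResult) -> str:
    rows = [
        {"gene": g, "tier": "shared_all" if g in result.shared_all else "conserved_any"}
        for g in sorted(result.conserved_any)
    ]
    return pd.DataFrame(rows, columns=["gene", "tier"]).to_csv(sep="\t", index=False)
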