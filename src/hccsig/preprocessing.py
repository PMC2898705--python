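"""Detection filtering, presence rule, quantile normalization and log transform.

The detection rule follows the chemiluminescent-array convention: a cell is
"present" iff S/N > 3 (strict) and quality flag < 5000 (strict); a gene
survives the presence filter iff it is present in at least half (non-strict)
of the samples of either compared group.  Undetected cells keep their
intensities — filtering acts on genes, not cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionExperiment, SampleDesign, ValidationError


@dataclass(frozen=True)
class DetectionThresholds:
    snr_min: float = 3.0
    qflag_max: int = 5000
    group_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.snr_min <= 0:
            raise ValidationError("snr_min must be positive")
        if not 0 < self.group_fraction <= 1:
            raise ValidationError("group_fraction must lie in (0, 1]")


def detect_calls(
    exp: ExpressionExperiment, thr: DetectionThresholds = DetectionThresholds()
) -> pd.DataFrame:
    """Boolean gene x sample detection matrix: S/N > snr_min AND flag < qflag_max."""
    return (exp.snr > thr.snr_min) & (exp.qflag < thr.qflag_max)


def presence_filter(
    detection: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    thr: DetectionThresholds = DetectionThresholds(),
) -> pd.Series:
    """Gene mask: detected in >= group_fraction of group A OR of group B."""
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValidationError("presence_filter requires two non-empty groups")
    frac_a = detection[a].mean(axis=1)
    frac_b = detection[b].mean(axis=1)
    return (frac_a >= thr.group_fraction) | (frac_b >= thr.group_fraction)


def quantile_normalize(exp: ExpressionExperiment) -> ExpressionExperiment:
    """Force every sample onto the mean empirical distribution.

    After normalization each sample's sorted intensity vector equals the
    across-sample mean of sorted vectors; ties within a sample receive the
    mean of the quantile values they would have occupied.
    """
    x = exp.intensities
    if x.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    values = x.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = ref
        # ties: average the quantile values assigned within each tied run
        s = pd.Series(mapped).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[:, j] = s
    return ExpressionExperiment(
        pd.DataFrame(out, index=x.index, columns=x.columns),
        exp.snr.copy(),
        exp.qflag.copy(),
        SampleDesign(exp.design.table.copy()),
    )


def log2_transform(exp: ExpressionExperiment, floor: float = 1.0) -> pd.DataFrame:
    """log2(max(intensity, floor)) as a gene x sample DataFrame."""
    if floor <= 0:
        raise ValidationError("floor must be positive")
    return np.log2(exp.intensities.clip(lower=floor))


def collapse_probes(
    exp: ExpressionExperiment, probe_to_gene: dict[str, str]
) -> ExpressionExperiment:
    """Collapse multiple probes per gene to the probe with max mean intensity.

    A convention, not a modeled choice: when several probes map to one gene
    the brightest (highest mean intensity) representative is kept and its
    row is relabeled with the gene id.  Unmapped probes keep their own ids.
    """
    gene_of = {p: probe_to_gene.get(p, p) for p in exp.gene_ids}
    means = exp.intensities.mean(axis=1)
    keep: dict[str, str] = {}
    for probe in exp.gene_ids:
        gene = gene_of[probe]
        if gene not in keep or means[probe] > means[keep[gene]]:
            keep[gene] = probe
    order = [p for p in exp.gene_ids if keep[gene_of[p]] == p]
    relabel = {p: gene_of[p] for p in order}

    def _take(m: pd.DataFrame) -> pd.DataFrame:
        out = m.loc[order].rename(index=relabel)
        out.index.name = "gene"
        return out

    return ExpressionExperiment(
        _take(exp.intensities),
        _take(exp.snr),
        _take(exp.qflag),
        SampleDesign(exp.design.table.copy()),
    )


def drop_samples(exp: ExpressionExperiment, sample_ids: Sequence[str]) -> ExpressionExperiment:
    """Exclude named samples (the quality-exclusion stand-in)."""
    keep = [s for s in exp.sample_ids if s not in set(sample_ids)]
    if len(keep) == len(exp.sample_ids):
        return exp
    return exp.subset_samples(keep)
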