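"""Intersect signature gene loci with copy-number-alteration regions.

A gene is copy-number supported iff its locus overlaps any CNA interval on
the same chromosome by at least one base (0-based half-open coordinates; a
minimum overlap fraction of the gene locus can be required instead).  The
interval search runs on an interval tree; its contract is output equality
with the all-pairs brute force.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, ValidationError


@dataclass
class CnaAnnotation:
    gene: str
    locus: GenomicInterval
    hits: list[GenomicInterval] = field(default_factory=list)

    @property
    def in_cna(self) -> bool:
        return bool(self.hits)


def map_genes_to_loci(
    gene_list: Sequence[str], locus_table: Mapping[str, GenomicInterval] | Iterable[GenomicInterval]
) -> tuple[dict[str, GenomicInterval], list[str]]:
    """Resolve gene loci from a locus table; report uncovered genes.

    Accepts either a mapping or an interval list whose names are gene ids;
    duplicate locus rows for one gene are an error.
    """
    if isinstance(locus_table, Mapping):
        table = dict(locus_table)
    else:
        table = {}
        for iv in locus_table:
            if iv.name in table:
                raise ValidationError(f"duplicate locus rows for gene {iv.name!r}")
            table[iv.name] = iv
    mapped = {g: table[g] for g in gene_list if g in table}
    missing = [g for g in gene_list if g not in table]
    return mapped, missing


def intersect_cna(
    gene_loci: Mapping[str, GenomicInterval],
    cna_regions: Sequence[GenomicInterval],
    min_overlap_fraction: float = 0.0,
) -> tuple[list[CnaAnnotation], float]:
    """Annotate each gene with its overlapping CNA intervals.

    Returns the annotations plus ``fraction_in_cna`` (overlapping genes /
    mapped genes; 0.0 for an empty input).  With the default
    ``min_overlap_fraction = 0`` a single shared base counts.
    """
    if not 0 <= min_overlap_fraction <= 1:
        raise ValidationError("min_overlap_fraction must lie in [0, 1]")
    trees: dict[str, IntervalTree] = {}
    for region in cna_regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, region
        )
    annotations: list[CnaAnnotation] = []
    n_in = 0
    for gene in sorted(gene_loci):
        locus = gene_loci[gene]
        hits = []
        tree = trees.get(locus.chrom)
        if tree is not None:
            for hit in sorted(tree.overlap(locus.start, locus.end)):
                region = hit.data
                overlap = min(locus.end, region.end) - max(locus.start, region.start)
                required = min_overlap_fraction * (locus.end - locus.start)
                if overlap >= max(1, required):
                    hits.append(region)
        annotations.append(CnaAnnotation(gene, locus, hits))
        n_in += bool(hits)
    fraction = n_in / len(annotations) if annotations else 0.0
    return annotations, fraction


def cna_annotation_tsv(annotations: Sequence[CnaAnnotation]) -> str:
    rows = [
        {
            "gene": a.gene,
            "chrom": a.locus.chrom,
            "start": a.locus.start,
            "end": a.locus.end,
            "n_hits": len(a.hits),
            "in_cna": a.in_cna,
        }
        for a in annotations
    ]
    cols = ["gene", "chrom", "start", "end", "n_hits", "in_cna"]
    return pd.DataFrame(rows, columns=cols).to_csv(sep="\t", index=False)


def cna_summary_json(annotations: Sequence[CnaAnnotation], fraction: float) -> str:
    return json.dumps(
        {
            "n_genes": len(annotations),
            "n_in_cna": sum(a.in_cna for a in annotations),
            "fraction_in_cna": fraction,
        },
        indent=2,
        sort_keys=True,
    )
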