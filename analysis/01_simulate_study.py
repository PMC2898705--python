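#!/usr/bin/env python
"""Generate the synthetic study and summarize what was planted.

Emulates the design: 24 rat liver samples in a 2 (age) x 3 (treatment:
early HCC / regenerated / normal) factorial with 4 replicates per cell,
plus three independent human case/control cohorts reached through an
ortholog table, CNA regions, and a qPCR panel.  Writes the planted-truth
summary to results/; the raw matrices regenerate deterministically from the
seed, so they are not stored.
"""

import argparse
from pathlib import Path

import pandas as pd

from hccsig.synthetic import (
    GeneratorParams,
    generate_cna_bed,
    generate_human_datasets,
    generate_ortholog_table,
    generate_rat_experiment,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int) -> None:
    params = GeneratorParams(seed=seed)
    exp, truth = generate_rat_experiment(params)
    ortho = generate_ortholog_table(truth, params)
    cohorts, de_truth = generate_human_datasets(truth, ortho, params)
    cna = generate_cna_bed(truth, params)

    print(f"rat experiment: {exp.shape[0]} genes x {exp.shape[1]} samples")
    cells = exp.design.table.groupby(["treatment", "age"]).size()
    print(f"design cells (samples each): {dict(cells)}")
    counts = truth.table["gene_class"].value_counts()
    print(f"planted classes: {counts.to_dict()}")
    print(f"ortholog table: {len(ortho)} mapped rat genes -> {len(ortho.targets)} symbols")
    for c in cohorts:
        n_case = len(c.group_samples("CASE"))
        n_ctrl = len(c.group_samples("CONTROL"))
        print(f"human cohort {c.name}: {n_case} cases / {n_ctrl} controls, "
              f"{len(de_truth[c.name])} planted DE orthologs")
    print(f"CNA regions: {len(cna)} intervals covering {len(truth.cna_genes)} flagged loci")

    RESULTS.mkdir(exist_ok=True)
    summary = counts.rename("n_genes").to_frame()
    summary["mean_abs_effect_log2"] = [
        truth.table.loc[truth.table["gene_class"] == k, "effect_log2"].abs().mean()
        for k in summary.index
    ]
    summary.to_csv(RESULTS / "01_planted_truth_summary.tsv", sep="\t", index_label="gene_class")
    print(f"wrote {RESULTS / '01_planted_truth_summary.tsv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
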