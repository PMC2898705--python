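from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hccsig.io_formats import ExpressionExperiment, SampleDesign
from hccsig.synthetic import GeneratorParams, generate_rat_experiment


def make_design(n_per_cell: int = 2) -> SampleDesign:
    rows = []
    for age in ("YOUNG", "OLD"):
        for treatment in ("HCC", "REG", "NORM"):
            for i in range(n_per_cell):
                rows.append((f"{age[0]}_{treatment}_{i}", treatment, age))
    df = pd.DataFrame(rows, columns=["sample_id", "treatment", "age"]).set_index("sample_id")
    return SampleDesign(df)


def make_experiment(
    intensities: np.ndarray,
    design: SampleDesign,
    snr: np.ndarray | None = None,
    qflag: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
) -> ExpressionExperiment:
    n_genes, n_samples = intensities.shape
    genes = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    cols = design.sample_ids[:n_samples]
    idx = pd.Index(genes, name="gene")
    return ExpressionExperiment(
        pd.DataFrame(intensities, index=idx, columns=cols),
        pd.DataFrame(snr if snr is not None else np.full_like(intensities, 10.0), index=idx, columns=cols),
        pd.DataFrame(qflag if qflag is not None else np.zeros_like(intensities), index=idx, columns=cols),
        design.subset(cols),
    )


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams(seed=11)


@pytest.fixture(scope="session")
def rat_run(default_params):
    """One full-size rat experiment shared across read-only tests."""
    return generate_rat_experiment(default_params)


@pytest.fixture()
def small_rat():
    params = GeneratorParams(
        seed=5, n_genes=120, n_hcc_up=6, n_hcc_down=3, n_reg_specific=4,
        n_age_only=10, n_interaction=4,
    )
    exp, truth = generate_rat_experiment(params)
    return params, exp, truth
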