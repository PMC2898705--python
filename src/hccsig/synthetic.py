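"""Seeded generators for every input the pipeline consumes, with planted truth.

The rat generator emulates a balanced 2 (age: young/old) x 3 (treatment:
early HCC / regenerated liver / normal liver) factorial microarray study of
24 samples (4 per cell): log-normal intensity background, Gaussian noise on
the log2 scale, planted gene classes (tumor-specific up/down, regeneration-
specific, age-only, age x treatment interaction, null) and independent
Bernoulli detection dropout on the per-cell S/N and quality-flag statistics.
Human case/control cohorts carry a configurable planted-conservation pattern
through an ortholog table; CNA BED regions cover exactly the loci of genes
flagged in-CNA; Ct tables plant triplicate qPCR measurements consistent with
the expression fold changes.

Every output is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AGES,
    TREATMENTS,
    CohortExperiment,
    CtTable,
    ExpressionExperiment,
    GenomicInterval,
    OrthologTable,
    SampleDesign,
    ValidationError,
)

CLASSES = ("HCC_UP", "HCC_DOWN", "REG_SPECIFIC", "AGE_ONLY", "INTERACTION", "NULL")
DATASETS = ("D1", "D2", "D3")

# distinct deterministic sub-streams per generator operation
_STREAM_RAT, _STREAM_ORTHO, _STREAM_HUMAN, _STREAM_CNA, _STREAM_CT = range(1, 6)

_GENES_PER_CHROM = 100
_LOCUS_SPACING = 100_000
_LOCUS_LENGTH = 10_000


@dataclass
class GeneratorParams:
    """All knobs of the synthetic study, with the study's defaults.

    Planted class counts default to roughly the proportions a ~27k-gene
    liver study reports, rescaled to the 2000-gene desk size; effects are
    log2 shifts of 2 (4-fold), within-group noise 0.25 on the log2 scale.
    """

    seed: int
    n_genes: int = 2000
    n_per_cell: int = 4
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.25
    n_hcc_up: int = 30
    n_hcc_down: int = 15
    n_reg_specific: int = 25
    n_age_only: int = 200
    n_interaction: int = 25
    effect_log2: float = 2.0
    effect_log2_range: tuple[float, float] | None = None  # per-gene magnitudes if set
    detection_dropout_rate: float = 0.05
    ortholog_fraction: float = 0.9
    human_cases: tuple[int, int, int] = (19, 16, 20)
    human_controls: tuple[int, int, int] = (10, 19, 10)
    conservation_fractions: tuple[float, float, float] = (0.5, 0.5, 0.5)
    human_noise_sd: float = 0.5
    cna_cover_fraction: float = 0.5
    cna_margin: int = 500
    ct_noise_sd: float = 0.2
    ct_samples_per_group: int = 4
    reference_gene: str = "Gapdh"

    def __post_init__(self) -> None:
        counts = (
            self.n_hcc_up,
            self.n_hcc_down,
            self.n_reg_specific,
            self.n_age_only,
            self.n_interaction,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("planted class counts must be >= 0")
        if sum(counts) > self.n_genes:
            raise ValidationError(
                f"planted class counts sum to {sum(counts)} > n_genes = {self.n_genes}"
            )
        if self.n_per_cell < 2:
            raise ValidationError("need >= 2 replicates per cell for variance estimates")
        if self.baseline_log2_sd < 0 or self.noise_sd < 0 or self.human_noise_sd < 0:
            raise ValidationError("standard deviations must be non-negative")
        if not 0 <= self.detection_dropout_rate < 1:
            raise ValidationError("detection_dropout_rate must lie in [0, 1)")
        if not 0 <= self.cna_cover_fraction <= 1:
            raise ValidationError("cna_cover_fraction must lie in [0, 1]")
        if not 0 < self.ortholog_fraction <= 1:
            raise ValidationError("ortholog_fraction must lie in (0, 1]")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["effect_log2_range"] is not None:
            d["effect_log2_range"] = list(d["effect_log2_range"])
        for k in ("human_cases", "human_controls", "conservation_fractions"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        if d.get("effect_log2_range") is not None:
            d["effect_log2_range"] = tuple(d["effect_log2_range"])
        for k in ("human_cases", "human_controls", "conservation_fractions"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth; what every recovery test asserts against.

    One row per gene: class, signed planted log2 effect, which human datasets
    carry the effect (HCC-class genes only), the in-CNA flag and the locus.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        null_bad = t.loc[(t["gene_class"] == "NULL") & (t["effect_log2"] != 0)]
        if len(null_bad):
            raise ValidationError("NULL genes must have effect_log2 = 0")
        cons = t[[f"conserved_{d}" for d in DATASETS]].any(axis=1)
        non_hcc = ~t["gene_class"].isin(("HCC_UP", "HCC_DOWN"))
        if (cons & non_hcc).any():
            raise ValidationError("conserved_in must be empty for non-HCC genes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def genes_in_class(self, *classes: str) -> list[str]:
        return list(self.table.index[self.table["gene_class"].isin(classes)])

    @property
    def hcc_genes(self) -> list[str]:
        return self.genes_in_class("HCC_UP", "HCC_DOWN")

    def conserved_in(self, gene: str) -> frozenset[str]:
        row = self.table.loc[gene]
        return frozenset(d for d in DATASETS if row[f"conserved_{d}"])

    def loci(self, genes: Sequence[str] | None = None) -> dict[str, GenomicInterval]:
        sub = self.table if genes is None else self.table.loc[list(genes)]
        return {
            g: GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), g)
            for g, r in sub.iterrows()
        }

    @property
    def cna_genes(self) -> list[str]:
        return list(self.table.index[self.table["in_cna"]])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"rg{i + 1:0{width}d}" for i in range(n)]


def _assign_loci(gene_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(gene_ids):
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        start = (i % _GENES_PER_CHROM) * _LOCUS_SPACING
        rows.append((g, chrom, start, start + _LOCUS_LENGTH))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")


def _build_truth(params: GeneratorParams, rng: np.random.Generator) -> SyntheticTruth:
    n = params.n_genes
    gene_ids = _gene_ids(n)
    order = rng.permutation(n)
    classes = np.full(n, "NULL", dtype=object)
    counts = [
        ("HCC_UP", params.n_hcc_up),
        ("HCC_DOWN", params.n_hcc_down),
        ("REG_SPECIFIC", params.n_reg_specific),
        ("AGE_ONLY", params.n_age_only),
        ("INTERACTION", params.n_interaction),
    ]
    pos = 0
    for name, count in counts:
        classes[order[pos : pos + count]] = name
        pos += count

    if params.effect_log2_range is not None:
        lo, hi = params.effect_log2_range
        magnitude = rng.uniform(lo, hi, size=n)
    else:
        magnitude = np.full(n, float(params.effect_log2))
    sign = np.where(classes == "HCC_DOWN", -1.0, 1.0)
    random_sign_classes = np.isin(classes, ("REG_SPECIFIC", "AGE_ONLY", "INTERACTION"))
    sign = np.where(random_sign_classes, rng.choice([-1.0, 1.0], size=n), sign)
    effect = np.where(classes == "NULL", 0.0, sign * magnitude)

    # interaction genes perturb a single non-tumor (treatment, age) cell:
    # they emulate age-modulated regeneration / normal-liver programs, so the
    # HCC signature's specificity is assertable against them.
    non_tumor_cells = [f"{t}:{a}" for t in ("REG", "NORM") for a in AGES]
    inter_cell = np.where(
        classes == "INTERACTION", rng.choice(non_tumor_cells, size=n), ""
    )

    is_hcc = np.isin(classes, ("HCC_UP", "HCC_DOWN"))
    conserved = {}
    for d, frac in zip(DATASETS, params.conservation_fractions):
        conserved[f"conserved_{d}"] = is_hcc & (rng.random(n) < frac)

    in_cna = np.zeros(n, dtype=bool)
    hcc_idx = np.flatnonzero(is_hcc)
    n_cna = int(round(params.cna_cover_fraction * len(hcc_idx)))
    if n_cna:
        in_cna[rng.choice(hcc_idx, size=n_cna, replace=False)] = True

    table = pd.DataFrame(
        {
            "gene_class": classes,
            "effect_log2": effect,
            **conserved,
            "in_cna": in_cna,
            "interaction_cell": inter_cell,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return SyntheticTruth(table.join(_assign_loci(gene_ids)))


def _design_table(n_per_cell: int) -> pd.DataFrame:
    rows = []
    for age in AGES:
        for treatment in TREATMENTS:
            for i in range(1, n_per_cell + 1):
                rows.append((f"{age[0]}_{treatment}_{i}", treatment, age))
    return pd.DataFrame(rows, columns=["sample_id", "treatment", "age"]).set_index(
        "sample_id"
    )


def generate_rat_experiment(
    params: GeneratorParams,
) -> tuple[ExpressionExperiment, SyntheticTruth]:
    """Generate the balanced 2 x 3 x n_per_cell rat experiment.

    HCC_UP/HCC_DOWN genes are shifted by their signed effect in HCC samples
    of both ages; REG_SPECIFIC only in regenerated samples; AGE_ONLY in all
    old samples; INTERACTION in exactly one non-tumor (treatment, age) cell.
    Intensities are ``2 ** (baseline + effects + noise)``; a random
    ``detection_dropout_rate`` fraction of cells is made undetectable by
    assigning S/N <= 3 or quality flag >= 5000.
    """
    rng = np.random.default_rng([params.seed, _STREAM_RAT])
    truth = _build_truth(params, rng)
    design_df = _design_table(params.n_per_cell)
    design = SampleDesign(design_df)
    n_genes, n_samples = params.n_genes, len(design_df)

    treatment = design_df["treatment"].to_numpy()
    age = design_df["age"].to_numpy()
    is_hcc_s = treatment == "HCC"
    is_reg_s = treatment == "REG"
    is_old_s = age == "OLD"

    effect = truth.table["effect_log2"].to_numpy()
    classes = truth.table["gene_class"].to_numpy()
    # per-gene mask of samples carrying the planted shift
    mask = np.zeros((n_genes, n_samples), dtype=bool)
    mask |= np.isin(classes, ("HCC_UP", "HCC_DOWN"))[:, None] & is_hcc_s[None, :]
    mask |= (classes == "REG_SPECIFIC")[:, None] & is_reg_s[None, :]
    mask |= (classes == "AGE_ONLY")[:, None] & is_old_s[None, :]
    cell_key = np.array([f"{t}:{a}" for t, a in zip(treatment, age)])
    inter = truth.table["interaction_cell"].to_numpy()
    mask |= (classes == "INTERACTION")[:, None] & (inter[:, None] == cell_key[None, :])
    shift = mask * effect[:, None]

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n_genes)
    log2 = baseline[:, None] + shift + rng.normal(0.0, params.noise_sd, (n_genes, n_samples))
    intensities = np.power(2.0, log2)

    snr = rng.uniform(5.0, 50.0, (n_genes, n_samples))
    qflag = rng.integers(0, 1000, (n_genes, n_samples)).astype(float)
    dropout = rng.random((n_genes, n_samples)) < params.detection_dropout_rate
    low_snr = rng.random((n_genes, n_samples)) < 0.5
    snr[dropout & low_snr] = rng.uniform(0.0, 3.0, int((dropout & low_snr).sum()))
    qflag[dropout & ~low_snr] = rng.integers(
        5000, 10000, int((dropout & ~low_snr).sum())
    ).astype(float)

    gene_index = pd.Index(truth.gene_ids, name="gene")
    cols = design_df.index
    exp = ExpressionExperiment(
        pd.DataFrame(intensities, index=gene_index, columns=cols),
        pd.DataFrame(snr, index=gene_index, columns=cols),
        pd.DataFrame(qflag, index=gene_index, columns=cols),
        design,
    )
    return exp, truth


def generate_ortholog_table(truth: SyntheticTruth, params: GeneratorParams) -> OrthologTable:
    """One-to-one rat -> human symbol map over a random mappable subset."""
    rng = np.random.default_rng([params.seed, _STREAM_ORTHO])
    genes = truth.gene_ids
    n_mapped = int(round(params.ortholog_fraction * len(genes)))
    if n_mapped == 0:
        raise ValidationError("ortholog_fraction leaves no mappable genes")
    mapped = sorted(rng.choice(len(genes), size=n_mapped, replace=False))
    rows = [(genes[i], genes[i].replace("rg", "HG").upper()) for i in mapped]
    return OrthologTable.from_rows(rows)


def generate_human_datasets(
    truth: SyntheticTruth,
    ortho: OrthologTable,
    params: GeneratorParams,
) -> tuple[list[CohortExperiment], dict[str, set[str]]]:
    """Three independent human case/control cohorts on the ortholog namespace.

    For dataset d, every HCC-class gene whose ``conserved_in`` contains d is
    shifted in cases by the same signed log2 effect it carries in the rat
    experiment.  Returns the cohorts plus the per-dataset planted DE truth
    (human symbols).
    """
    if not ortho.mapping:
        raise ValidationError("ortholog table is empty")
    for n_case, n_control in zip(params.human_cases, params.human_controls):
        if n_case < 2 or n_control < 2:
            raise ValidationError("each human dataset needs >= 2 cases and >= 2 controls")
    rng = np.random.default_rng([params.seed, _STREAM_HUMAN])
    symbols = sorted(ortho.targets)
    # first-listed rat source wins for many-to-one maps, matching the table rule
    src_of: dict[str, str] = {}
    for rat_gene, symbol in ortho.mapping.items():
        src_of.setdefault(symbol, rat_gene)

    effect = truth.table["effect_log2"]
    cohorts: list[CohortExperiment] = []
    de_truth: dict[str, set[str]] = {}
    for d_idx, d in enumerate(DATASETS):
        n_case = params.human_cases[d_idx]
        n_control = params.human_controls[d_idx]
        conserved_col = truth.table[f"conserved_{d}"]
        shifts = np.array(
            [
                effect[src_of[s]] if conserved_col[src_of[s]] else 0.0
                for s in symbols
            ]
        )
        de_truth[d] = {s for s, sh in zip(symbols, shifts) if sh != 0.0}
        n_samples = n_case + n_control
        is_case = np.arange(n_samples) < n_case
        baseline = rng.normal(
            params.baseline_log2_mean, params.baseline_log2_sd, len(symbols)
        )
        log2 = (
            baseline[:, None]
            + shifts[:, None] * is_case[None, :]
            + rng.normal(0.0, params.human_noise_sd, (len(symbols), n_samples))
        )
        sample_ids = [
            f"{d}_{'case' if c else 'ctrl'}_{i + 1}"
            for i, c in enumerate(is_case)
        ]
        labels = pd.Series(
            np.where(is_case, "CASE", "CONTROL"),
            index=pd.Index(sample_ids, name="sample_id"),
            name="group",
        )
        cohorts.append(
            CohortExperiment(
                pd.DataFrame(
                    np.power(2.0, log2),
                    index=pd.Index(symbols, name="gene"),
                    columns=sample_ids,
                ),
                labels,
                name=d,
            )
        )
    return cohorts, de_truth


def generate_cna_bed(
    truth: SyntheticTruth,
    params: GeneratorParams,
    max_retries: int = 8,
) -> list[GenomicInterval]:
    """CNA intervals covering exactly the loci of in-CNA genes.

    Each interval is the gene locus padded by ``cna_margin``; if padding
    would also cover a non-CNA gene locus the margin is halved (up to
    ``max_retries`` times) before erroring out.
    """
    cna_genes = truth.cna_genes
    if not cna_genes:
        return []
    loci = truth.loci()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in loci.values():
        by_chrom.setdefault(iv.chrom, []).append(iv)
    cna_set = set(cna_genes)
    intervals: list[GenomicInterval] = []
    for k, gene in enumerate(sorted(cna_genes)):
        locus = loci[gene]
        margin = params.cna_margin
        for _ in range(max_retries + 1):
            padded = GenomicInterval(
                locus.chrom, max(0, locus.start - margin), locus.end + margin, f"cna_{k + 1}"
            )
            collision = any(
                padded.overlaps(other)
                for other in by_chrom[locus.chrom]
                if other.name not in cna_set
            )
            if not collision:
                intervals.append(padded)
                break
            if margin == 0:
                raise ValidationError(
                    f"cannot place CNA interval for {gene} without covering a non-CNA locus"
                )
            margin //= 2
        else:
            raise ValidationError(
                f"cannot place CNA interval for {gene} within {max_retries} retries"
            )
    return intervals


def generate_ct_table(
    truth: SyntheticTruth,
    gene_subset: Sequence[str],
    params: GeneratorParams,
    n_replicates: int = 3,
) -> CtTable:
    """Triplicate qPCR Ct values consistent with the planted log2 effects.

    Case samples of a target gene sit ``effect_log2`` cycles lower than
    controls (one PCR cycle per log2 unit of expression), the reference gene
    is unshifted, and every Ct carries Gaussian noise ``ct_noise_sd``.
    """
    genes = list(gene_subset)
    if not genes:
        raise ValidationError("gene_subset is empty")
    unknown = set(genes) - set(truth.gene_ids)
    if unknown:
        raise ValidationError(f"genes not in truth: {sorted(unknown)[:5]}")
    rng = np.random.default_rng([params.seed, _STREAM_CT])
    effect = truth.table["effect_log2"]
    all_genes = genes + [params.reference_gene]
    base_ct = {g: rng.uniform(18.0, 28.0) for g in all_genes}
    rows = []
    for group, tag in (("CASE", "case"), ("CONTROL", "ctrl")):
        for s in range(1, params.ct_samples_per_group + 1):
            sample = f"{tag}_{s}"
            for g in all_genes:
                true_ct = base_ct[g]
                if group == "CASE" and g != params.reference_gene:
                    true_ct -= effect[g]
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        (
                            g,
                            sample,
                            group,
                            rep,
                            true_ct + rng.normal(0.0, params.ct_noise_sd),
                        )
                    )
    table = pd.DataFrame(rows, columns=["gene", "sample", "group", "replicate", "ct"])
    return CtTable(table, reference_gene=params.reference_gene)
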