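"""End-to-end orchestration plus clustering/PCA reporting.

``run_pipeline`` executes simulate -> preprocess -> differential expression
-> signature -> conservation -> CNA integration -> enrichment -> qPCR ->
reports, writing every stage's artifacts and a checksum manifest; a rerun
with an identical configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from . import cna_integration, conservation, qpcr, synthetic
from .diffexp import fold_change, two_way_anova
from .enrichment import enrich, enrichment_tsv
from .io_formats import (
    AGES,
    ExpressionExperiment,
    ValidationError,
    write_results_bundle,
)
from .preprocessing import DetectionThresholds, log2_transform, quantile_normalize
from .signature import (
    Thresholds,
    combine_signature,
    cross_age_template_match,
    signature_tsv,
    step1_signature,
    step2_signature,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# clustering / PCA reports
# ---------------------------------------------------------------------------


def hier_cluster(
    log_matrix: pd.DataFrame, axis: str = "samples", k: int | None = None
) -> dict[str, Any]:
    """Average-linkage hierarchical clustering on 1 - Pearson distances.

    ``axis`` selects whether samples (columns) or genes (rows) are the
    clustered items; a constant item (zero variance, undefined correlation)
    is a validation error naming it.  Returns the linkage matrix, item
    names, and flat labels when ``k`` is given.
    """
    if axis not in ("samples", "genes"):
        raise ValidationError("axis must be 'samples' or 'genes'")
    items = log_matrix.T if axis == "samples" else log_matrix
    if items.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    variances = items.var(axis=1, ddof=0)
    constant = variances.index[variances == 0].tolist()
    if constant:
        raise ValidationError(f"constant item(s) cannot be correlated: {constant[:5]}")
    dist = pdist(items.to_numpy(dtype=float), metric="correlation")
    linkage = hierarchy.average(dist)
    out: dict[str, Any] = {"linkage": linkage, "items": list(items.index)}
    if k is not None:
        out["labels"] = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return out


def pca_report(log_matrix: pd.DataFrame, n_components: int = 3) -> dict[str, Any]:
    """Principal components of the gene-centered sample cloud.

    Variance fractions are non-increasing and sum to <= 1; ``scores`` holds
    the per-sample coordinates on the leading components.
    """
    if log_matrix.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    x = log_matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2
    rank = int((ev > ev[0] * 1e-12).sum()) if ev.size and ev[0] > 0 else 0
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; truncating", n_components, rank)
        n_components = rank
    fractions = ev[:n_components] / ev.sum() if ev.sum() > 0 else ev[:n_components]
    scores = (vt[:n_components].T * s[:n_components])
    return {
        "variance_fractions": fractions,
        "scores": pd.DataFrame(
            scores,
            index=log_matrix.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
    }


def separation_score(true_labels: Sequence, cluster_labels: Sequence) -> float:
    """Adjusted Rand index between a known partition and a clustering."""
    a = list(true_labels)
    b = list(cluster_labels)
    if len(a) != len(b):
        raise ValidationError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from the YAML run config."""

    generator: synthetic.GeneratorParams
    thresholds: Thresholds = field(default_factory=Thresholds)
    detection: DetectionThresholds = field(default_factory=DetectionThresholds)
    quantile_normalization: bool = True
    drop_samples: tuple[str, ...] = ()
    conservation_alpha: float = 0.001
    conservation_fc_min: float | None = None
    direction_matched: bool = False
    enrichment_alpha: float = 0.05
    qpcr_panel_size: int = 8
    log2_floor: float = 1.0

    @property
    def seed(self) -> int:
        return self.generator.seed

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "generator": self.generator.to_dict(),
            "thresholds": {
                "alpha_treatment": self.thresholds.alpha_treatment,
                "alpha_tm": self.thresholds.alpha_tm,
                "alpha_stratified": self.thresholds.alpha_stratified,
                "fc_min": self.thresholds.fc_min,
                "use_omnibus_gate": self.thresholds.use_omnibus_gate,
            },
            "detection": {
                "snr_min": self.detection.snr_min,
                "qflag_max": self.detection.qflag_max,
                "group_fraction": self.detection.group_fraction,
            },
            "quantile_normalization": self.quantile_normalization,
            "drop_samples": list(self.drop_samples),
            "conservation": {
                "alpha": self.conservation_alpha,
                "fc_min": self.conservation_fc_min,
                "direction_matched": self.direction_matched,
            },
            "enrichment": {"alpha": self.enrichment_alpha},
            "qpcr": {"panel_size": self.qpcr_panel_size},
            "log2_floor": self.log2_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        gen = dict(d.get("generator", {}))
        if "seed" not in gen:
            if "seed" not in d:
                raise ValidationError("config must set a seed")
            gen["seed"] = d["seed"]
        cons = d.get("conservation", {})
        return cls(
            generator=synthetic.GeneratorParams.from_dict(gen),
            thresholds=Thresholds(**d.get("thresholds", {})),
            detection=DetectionThresholds(**d.get("detection", {})),
            quantile_normalization=d.get("quantile_normalization", True),
            drop_samples=tuple(d.get("drop_samples", ())),
            conservation_alpha=cons.get("alpha", 0.001),
            conservation_fc_min=cons.get("fc_min"),
            direction_matched=cons.get("direction_matched", False),
            enrichment_alpha=d.get("enrichment", {}).get("alpha", 0.05),
            qpcr_panel_size=d.get("qpcr", {}).get("panel_size", 8),
            log2_floor=d.get("log2_floor", 1.0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")
        return path


# ---------------------------------------------------------------------------
# signature derivation (library entry point shared by CLI and scripts)
# ---------------------------------------------------------------------------


def derive_signature(
    exp: ExpressionExperiment,
    thresholds: Thresholds = Thresholds(),
    detection: DetectionThresholds = DetectionThresholds(),
    quantile: bool = True,
    floor: float = 1.0,
) -> dict[str, Any]:
    """Run the full two-step derivation on one factorial experiment.

    Returns the combined signature plus every intermediate (normalized
    experiment, log2 matrix, ANOVA table, cross-age template match, per-age
    entries and pairwise DE sets).
    """
    norm = quantile_normalize(exp) if quantile else exp
    log_m = log2_transform(norm, floor=floor)
    anova = two_way_anova(log_m, norm.design)
    tm = cross_age_template_match(log_m, norm.design)
    step1 = step1_signature(anova, tm, thresholds)
    step2 = {}
    pairwise = {}
    for age_level in AGES:
        cohort = norm.subset_samples(norm.design.samples(age=age_level))
        entries, sets = step2_signature(cohort, age_level, thresholds, detection)
        step2[age_level] = entries
        pairwise[age_level] = sets
    signature = combine_signature(step1, step2["YOUNG"], step2["OLD"])
    return {
        "experiment": norm,
        "log2": log_m,
        "anova": anova,
        "template_match": tm,
        "step1": step1,
        "step2": step2,
        "pairwise_sets": pairwise,
        "signature": signature,
    }


def _synthetic_gene_sets(
    truth: synthetic.SyntheticTruth, seed: int, n_random: int = 10, random_size: int = 50
) -> dict[str, list[str]]:
    """Gene-set collection for the enrichment stage of a synthetic run:
    the planted classes as sets plus seeded random decoys."""
    rng = np.random.default_rng([seed, 97])
    sets: dict[str, list[str]] = {}
    for name, classes in {
        "planted_hcc_up": ("HCC_UP",),
        "planted_hcc_down": ("HCC_DOWN",),
        "planted_regeneration": ("REG_SPECIFIC",),
        "planted_age": ("AGE_ONLY",),
    }.items():
        members = truth.genes_in_class(*classes)
        if members:
            sets[name] = sorted(members)
    genes = np.array(truth.gene_ids)
    for i in range(n_random):
        members = rng.choice(genes, size=min(random_size, len(genes)), replace=False)
        sets[f"random_set_{i + 1:02d}"] = sorted(members)
    return sets


def _cohort_ari(
    exp: ExpressionExperiment, log_m: pd.DataFrame, anova: pd.DataFrame, alpha: float
) -> dict[str, float]:
    """ARI of sample clustering (k = 3, treatment-significant genes) per age."""
    sig_genes = anova.index[(anova["p_treatment"] < alpha).fillna(False)]
    scores = {}
    for age_level in AGES:
        ids = exp.design.samples(age=age_level)
        sub = log_m.loc[sig_genes, ids]
        clustering = hier_cluster(sub, axis="samples", k=3)
        truth_labels = exp.design.table.loc[ids, "treatment"].tolist()
        scores[age_level] = separation_score(truth_labels, clustering["labels"])
    return scores


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the whole synthetic-mode pipeline and write the results bundle.

    Returns the in-memory stage outputs (truth, signature, conservation,
    CNA, enrichment, qPCR, reports) plus the written manifest.
    """
    artifacts: dict[str, str] = {}
    state: dict[str, Any] = {"config": config}
    stage = "init"
    t0 = time.time()
    try:
        stage = "simulate"
        params = config.generator
        exp, truth = synthetic.generate_rat_experiment(params)
        if config.drop_samples:
            exp = exp.subset_samples(
                [s for s in exp.sample_ids if s not in set(config.drop_samples)]
            )
        ortho = synthetic.generate_ortholog_table(truth, params)
        cohorts, de_truth = synthetic.generate_human_datasets(truth, ortho, params)
        cna_bed = synthetic.generate_cna_bed(truth, params)
        state.update(
            truth=truth, experiment=exp, ortholog=ortho, cohorts=cohorts,
            human_de_truth=de_truth, cna_bed=cna_bed,
        )

        stage = "signature"
        derived = derive_signature(
            exp,
            config.thresholds,
            config.detection,
            quantile=config.quantile_normalization,
            floor=config.log2_floor,
        )
        state["derived"] = derived
        signature = derived["signature"]
        artifacts["signature.tsv"] = signature_tsv(signature)

        stage = "conservation"
        mapped, unmapped = conservation.map_orthologs(signature, ortho)
        de_sets = {
            c.name: conservation.dataset_de_call(
                c, config.conservation_alpha, config.conservation_fc_min
            )
            for c in cohorts
        }
        if config.direction_matched:
            sig_dir = dict(zip(mapped["gene"], mapped["direction"]))
            for c in cohorts:
                directions = conservation.dataset_de_directions(
                    c, config.conservation_alpha, config.conservation_fc_min
                )
                de_sets[c.name] = {
                    g
                    for g in de_sets[c.name]
                    if g not in sig_dir or directions.get(g) == sig_dir[g]
                }
        universes = {c.name: set(c.gene_ids) & ortho.targets for c in cohorts}
        cons = conservation.conservation_tiers(set(mapped["gene"]), de_sets, universes)
        cons.unmapped = unmapped
        state.update(mapped_signature=mapped, conservation=cons, de_sets=de_sets)
        artifacts["overlap_tests.json"] = cons.to_json()
        artifacts["conservation_tiers.tsv"] = conservation.tiers_tsv(cons)

        stage = "cna"
        sig_genes = list(signature["gene"])
        loci, missing_loci = cna_integration.map_genes_to_loci(sig_genes, truth.loci())
        annotations, fraction = cna_integration.intersect_cna(loci, cna_bed)
        state.update(cna_annotations=annotations, fraction_in_cna=fraction,
                     missing_loci=missing_loci)
        artifacts["cna_annotation.tsv"] = cna_integration.cna_annotation_tsv(annotations)
        artifacts["cna_summary.json"] = cna_integration.cna_summary_json(
            annotations, fraction
        )

        stage = "enrichment"
        gene_sets = _synthetic_gene_sets(truth, params.seed)
        enr = enrich(sig_genes, gene_sets, truth.gene_ids, alpha=config.enrichment_alpha)
        state["enrichment"] = enr
        artifacts["enrichment.tsv"] = enrichment_tsv(enr)

        stage = "qpcr"
        panel = sorted(truth.hcc_genes)[: config.qpcr_panel_size]
        if panel:
            ct = synthetic.generate_ct_table(truth, panel, params)
            ddct = qpcr.delta_delta_ct(ct)
            ddct = ddct.drop(index=params.reference_gene, errors="ignore")
            arr_fc = fold_change(
                exp.intensities,
                exp.design.samples(treatment="HCC"),
                exp.design.samples(treatment="NORM"),
            )
            array_log2fc = np.log2(arr_fc.loc[ddct.index, "ratio"].to_numpy())
            r, p = qpcr.concordance(array_log2fc, ddct["log2fc"].to_numpy())
            state.update(ct_table=ct, ddct=ddct, concordance=(r, p))
            artifacts["qpcr_ddct.tsv"] = qpcr.ddct_tsv(ddct)
            artifacts["qpcr_concordance.json"] = qpcr.concordance_json(r, p, len(ddct))

        stage = "reports"
        ari = _cohort_ari(
            exp, derived["log2"], derived["anova"], config.thresholds.alpha_treatment
        )
        pca = pca_report(derived["log2"], n_components=3)
        state.update(ari=ari, pca=pca)
        artifacts["cluster_report.json"] = json.dumps(
            {
                "ari_by_age": ari,
                "pca_variance_fractions": [float(v) for v in pca["variance_fractions"]],
            },
            indent=2,
            sort_keys=True,
        )

        stage = "write"
        manifest = write_results_bundle(artifacts, out_dir, config.to_dict())
        state["manifest"] = manifest
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return state
    except Exception as exc:
        if stage != "write":
            try:
                write_results_bundle(artifacts, out_dir, config.to_dict(), failed_stage=stage)
            except Exception:  # noqa: BLE001 - preserve the primary failure
                pass
        raise PipelineError(stage, exc) from exc
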