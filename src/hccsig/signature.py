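"""Two-step HCC signature derivation.

Step 1 finds genes modulated by treatment (two-way ANOVA p < 0.01) whose
profiles match the binary HCC template in *both* age cohorts with the same
sign (template-match p < 0.01 per cohort) — the "conserved across young and
old" tumor profile.  Matching within each cohort separately is what makes
the step tumor-specific: a regeneration-driven gene only anti-matches the
pooled template weakly, and a single-age effect matches in one cohort only;
neither survives the two-cohort requirement.

Step 2 stratifies by age and intersects pairwise differential-expression
calls (presence rule, p < 0.02, |FC| > 1.8) in the Venn pattern
(HCC-vs-NORM ∩ HCC-vs-REG) \\ REG-vs-NORM, yielding genes dysregulated in
the tumor group only.  The two steps are unioned with provenance; direction
conflicts are flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import fold_change, one_way_anova, template_match, unpaired_t
from .io_formats import AGES, ExpressionExperiment, SampleDesign, ValidationError
from .preprocessing import DetectionThresholds, detect_calls, log2_transform, presence_filter

SOURCES = ("STEP1", "STEP2_YOUNG", "STEP2_OLD")
PAIRWISE_KEYS = ("D_vs_N", "D_vs_R", "R_vs_N")
_PAIRS = {"D_vs_N": ("HCC", "NORM"), "D_vs_R": ("HCC", "REG"), "R_vs_N": ("REG", "NORM")}


@dataclass(frozen=True)
class Thresholds:
    """Signature-call thresholds (all inequalities strict)."""

    alpha_treatment: float = 0.01
    alpha_tm: float = 0.01
    alpha_stratified: float = 0.02
    fc_min: float = 1.8
    use_omnibus_gate: bool = False  # also require the one-way ANOVA omnibus p

    def __post_init__(self) -> None:
        for name in ("alpha_treatment", "alpha_tm", "alpha_stratified"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.fc_min <= 1:
            raise ValidationError("fc_min must exceed 1")


def make_template(design: SampleDesign, target_treatment: str = "HCC") -> np.ndarray:
    """Binary template over the design's samples: 1 for the target condition."""
    return (design.table["treatment"] == target_treatment).to_numpy(dtype=float)


def cross_age_template_match(
    log_matrix: pd.DataFrame,
    design: SampleDesign,
    target_treatment: str = "HCC",
) -> pd.DataFrame:
    """Template match computed within each age cohort and combined.

    A gene's combined call requires the same match sign in both cohorts;
    the combined p is the worse (max) of the two cohort p-values, so a gene
    is significant only if it is significant in young *and* old.  Genes with
    discordant signs or an untestable cohort are reported untestable.
    """
    per_age = {}
    for age_level in AGES:
        ids = design.samples(age=age_level)
        if not ids:
            raise ValidationError(f"no samples with age {age_level!r}")
        sub_design = design.subset(ids)
        per_age[age_level] = template_match(
            log_matrix[ids], make_template(sub_design, target_treatment)
        )
    young, old = per_age["YOUNG"], per_age["OLD"]
    same_sign = (
        (young["direction"] == old["direction"])
        & (young["direction"] != "")
        & young["p"].notna()
        & old["p"].notna()
    )
    p = pd.concat([young["p"], old["p"]], axis=1).max(axis=1).where(same_sign)
    # report the weaker (smaller |r|) cohort correlation; signs agree when kept
    r_stack = np.column_stack([young["r"].to_numpy(), old["r"].to_numpy()])
    weaker = np.argmin(np.abs(np.nan_to_num(r_stack, nan=np.inf)), axis=1)
    r = pd.Series(r_stack[np.arange(len(r_stack)), weaker], index=log_matrix.index)
    r = r.where(same_sign)
    direction = young["direction"].where(same_sign, "")
    return pd.DataFrame({"r": r, "p": p, "direction": direction}, index=log_matrix.index)


def step1_signature(
    anova: pd.DataFrame, tm: pd.DataFrame, thr: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Genes with ANOVA treatment p < alpha AND template p < alpha (strict)."""
    if not anova.index.equals(tm.index):
        raise ValidationError("ANOVA and template-match results cover different genes")
    keep = (anova["p_treatment"] < thr.alpha_treatment) & (tm["p"] < thr.alpha_tm)
    keep &= anova["p_treatment"].notna() & tm["p"].notna()
    out = pd.DataFrame(
        {
            "gene": anova.index[keep],
            "direction": tm.loc[keep, "direction"].to_numpy(),
            "source": "STEP1",
        }
    )
    return out.reset_index(drop=True)


def pairwise_de_sets(
    cohort: ExpressionExperiment,
    thr: Thresholds = Thresholds(),
    det_thr: DetectionThresholds = DetectionThresholds(),
    floor: float = 1.0,
) -> dict[str, set[str]]:
    """The three stratified pairwise DE sets: D-vs-N, D-vs-R, R-vs-N.

    A gene enters a set iff it passes the presence rule for that comparison,
    the unpaired test at p < alpha_stratified, and |FC| > fc_min (all joint).
    """
    design = cohort.design
    groups = {t: design.samples(treatment=t) for t in ("HCC", "REG", "NORM")}
    for t, ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(f"treatment group {t!r} absent or < 2 samples in cohort")
    detection = detect_calls(cohort, det_thr)
    log_m = log2_transform(cohort, floor=floor)
    omnibus_ok = None
    if thr.use_omnibus_gate:
        om = one_way_anova(log_m, design)
        omnibus_ok = om["p"] < thr.alpha_stratified
    sets: dict[str, set[str]] = {}
    for key, (a, b) in _PAIRS.items():
        present = presence_filter(detection, groups[a], groups[b], det_thr)
        tt = unpaired_t(log_m, groups[a], groups[b])
        fc = fold_change(cohort.intensities, groups[a], groups[b])
        keep = present & (tt["p"] < thr.alpha_stratified) & (fc["abs_fc"] > thr.fc_min)
        keep &= tt["p"].notna()
        if omnibus_ok is not None:
            keep &= omnibus_ok
        sets[key] = set(log_m.index[keep])
    return sets


def venn_specific(set_dn: set[str], set_dr: set[str], set_rn: set[str]) -> set[str]:
    """HCC-specific genes: (D-vs-N ∩ D-vs-R) minus R-vs-N."""
    return (set_dn & set_dr) - set_rn


def regeneration_specific(set_dn: set[str], set_dr: set[str], set_rn: set[str]) -> set[str]:
    """Regeneration-specific genes: (R-vs-N ∩ D-vs-R) minus D-vs-N."""
    return (set_rn & set_dr) - set_dn


def step2_signature(
    cohort: ExpressionExperiment,
    age_level: str,
    thr: Thresholds = Thresholds(),
    det_thr: DetectionThresholds = DetectionThresholds(),
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Stratified Venn-specific signature entries for one age cohort.

    Directions come from the HCC-vs-NORM fold change within the cohort.
    Returns the entries plus the underlying pairwise DE sets.
    """
    if age_level not in AGES:
        raise ValidationError(f"unknown age level {age_level!r}")
    sets = pairwise_de_sets(cohort, thr, det_thr)
    specific = sorted(venn_specific(sets["D_vs_N"], sets["D_vs_R"], sets["R_vs_N"]))
    design = cohort.design
    fc = fold_change(
        cohort.intensities, design.samples(treatment="HCC"), design.samples(treatment="NORM")
    )
    entries = pd.DataFrame(
        {
            "gene": specific,
            "direction": fc.loc[specific, "direction"].to_numpy(),
            "source": f"STEP2_{age_level}",
        }
    )
    return entries, sets


def combine_signature(*entry_frames: pd.DataFrame) -> pd.DataFrame:
    """Union signature entries, accumulating sources and flagging conflicts.

    Idempotent and order-invariant: genes are sorted lexicographically and
    sources are a sorted, semicolon-joined set.  A gene whose sources
    disagree on direction keeps the first-seen direction (by source order)
    and is flagged ``conflicted``.
    """
    frames = [f for f in entry_frames if f is not None and len(f)]
    if not frames:
        return pd.DataFrame(columns=["gene", "direction", "sources", "conflicted"])
    all_entries = pd.concat(frames, ignore_index=True)
    if (all_entries["direction"] == "").any():
        raise ValidationError("every signature entry needs a direction")
    rows = []
    for gene, sub in all_entries.groupby("gene", sort=True):
        sub = sub.sort_values("source", key=lambda s: s.map(SOURCES.index))
        directions = list(dict.fromkeys(sub["direction"]))
        rows.append(
            {
                "gene": gene,
                "direction": directions[0],
                "sources": ";".join(sorted(set(sub["source"]), key=SOURCES.index)),
                "conflicted": len(directions) > 1,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "direction", "sources", "conflicted"])


def signature_tsv(signature: pd.DataFrame) -> str:
    """Deterministic TSV serialization (lexicographic gene order)."""
    out = signature.sort_values("gene").reset_index(drop=True)
    return out.to_csv(sep="\t", index=False)
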