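"""Readers and writers for every on-disk artifact the pipeline touches.

Canonical dialects: TSV (UTF-8, ``.`` for missing) for tabular data, BED
(0-based, half-open) for genomic coordinates, GMT for gene sets, JSON for
overlap tests and the run manifest, YAML for the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TREATMENTS = ("HCC", "REG", "NORM")
AGES = ("YOUNG", "OLD")
GROUPS = ("CASE", "CONTROL")

MISSING = "."


class ValidationError(ValueError):
    """Input violates a documented invariant (bad level, duplicate id, ...)."""


class StructuralError(ValueError):
    """Files that should describe one object disagree in shape or ordering."""


class ParseError(ValueError):
    """A line could not be parsed at all."""


# ---------------------------------------------------------------------------
# expression experiments
# ---------------------------------------------------------------------------


def _check_unique(values: Sequence[str], what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class SampleDesign:
    """Treatment (HCC/REG/NORM) and age (YOUNG/OLD) label per sample."""

    table: pd.DataFrame  # index: sample_id; columns: treatment, age

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["treatment", "age"]:
            missing = {"treatment", "age"} - set(t.columns)
            if missing:
                raise StructuralError(f"design table lacks columns {sorted(missing)}")
        _check_unique(t.index, "sample id")
        t.index.name = "sample_id"
        bad_t = set(t["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValidationError(f"unknown treatment level(s): {sorted(bad_t)}")
        bad_a = set(t["age"]) - set(AGES)
        if bad_a:
            raise ValidationError(f"unknown age level(s): {sorted(bad_a)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples(self, treatment: str | None = None, age: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if treatment is not None:
            mask &= self.table["treatment"] == treatment
        if age is not None:
            mask &= self.table["age"] == age
        return list(self.table.index[mask])

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(sample_ids)].copy())


@dataclass
class ExpressionExperiment:
    """Gene x sample intensities plus per-cell detection statistics.

    ``intensities`` are linear-scale, non-negative signal values; ``snr`` is
    the per-cell signal-to-noise ratio and ``qflag`` the platform quality
    flag, both used by the detection rule (S/N > 3 and flag < 5000).
    All three matrices share identical gene and sample orderings.
    """

    intensities: pd.DataFrame
    snr: pd.DataFrame
    qflag: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        base = self.intensities
        _check_unique(base.index, "gene id")
        _check_unique(base.columns, "sample id")
        for m in (self.intensities, self.snr, self.qflag):
            m.index.name = "gene"
            m.columns.name = None
        for name, m in (("snr", self.snr), ("qflag", self.qflag)):
            if m.shape != base.shape:
                raise StructuralError(
                    f"{name} matrix shape {m.shape} != intensities shape {base.shape}"
                )
            if not (m.index.equals(base.index) and m.columns.equals(base.columns)):
                raise StructuralError(f"{name} matrix row/column ids disagree with intensities")
        missing = set(base.columns) - set(self.design.sample_ids)
        if missing:
            raise ValidationError(f"design file missing sample id(s): {sorted(missing)[:5]}")
        # harmonize design ordering with the matrices
        self.design = SampleDesign(self.design.table.loc[list(base.columns)].copy())
        vals = base.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("intensities contain non-finite values")
        if (vals < 0).any():
            raise ValidationError("intensities must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionExperiment":
        ids = list(sample_ids)
        return ExpressionExperiment(
            self.intensities[ids].copy(),
            self.snr[ids].copy(),
            self.qflag[ids].copy(),
            self.design.subset(ids),
        )


@dataclass
class CohortExperiment:
    """A case/control expression cohort (human validation datasets)."""

    intensities: pd.DataFrame  # gene x sample, linear scale
    labels: pd.Series  # sample -> CASE / CONTROL
    name: str = "cohort"

    def __post_init__(self) -> None:
        _check_unique(self.intensities.index, "gene id")
        _check_unique(self.intensities.columns, "sample id")
        if not self.labels.index.equals(self.intensities.columns):
            self.labels = self.labels.loc[self.intensities.columns]
        bad = set(self.labels) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        for g in GROUPS:
            if (self.labels == g).sum() == 0:
                raise ValidationError(f"cohort {self.name!r} has no {g} samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.intensities.index)

    def group_samples(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    return df


def read_expression(
    matrix_path: str | Path,
    snr_path: str | Path,
    qflag_path: str | Path,
    design_path: str | Path,
) -> ExpressionExperiment:
    """Read the four TSV files describing one experiment and harmonize them.

    The first column of each matrix file holds gene ids and the header row
    sample ids; the design file maps every sample id to (treatment, age).
    """
    inten = _read_tsv_matrix(matrix_path)
    snr = _read_tsv_matrix(snr_path)
    qflag = _read_tsv_matrix(qflag_path)
    for name, path, m in (("snr", snr_path, snr), ("qflag", qflag_path, qflag)):
        if m.shape != inten.shape:
            raise StructuralError(
                f"{path}: shape {m.shape} does not match intensities {inten.shape}"
            )
        try:
            m_aligned = m.loc[inten.index, inten.columns]
        except KeyError as exc:
            raise StructuralError(f"{path}: ids do not match intensities: {exc}") from exc
        if name == "snr":
            snr = m_aligned
        else:
            qflag = m_aligned
    design_df = pd.read_csv(design_path, sep="\t", index_col=0, dtype=str)
    design_df.index = design_df.index.astype(str)
    return ExpressionExperiment(inten, snr, qflag, SampleDesign(design_df))


def write_expression(exp: ExpressionExperiment, out_dir: str | Path, prefix: str = "rat") -> dict:
    """Write the four-file TSV representation; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}_intensities.tsv",
        "snr": out / f"{prefix}_snr.tsv",
        "qflag": out / f"{prefix}_qflag.tsv",
        "design": out / f"{prefix}_design.tsv",
    }
    exp.intensities.to_csv(paths["matrix"], sep="\t", index_label="gene_id", na_rep=MISSING)
    exp.snr.to_csv(paths["snr"], sep="\t", index_label="gene_id", na_rep=MISSING)
    exp.qflag.to_csv(paths["qflag"], sep="\t", index_label="gene_id", na_rep=MISSING)
    exp.design.table.to_csv(paths["design"], sep="\t", index_label="sample_id")
    return paths


def read_cohort(matrix_path: str | Path, labels_path: str | Path, name: str = "cohort") -> CohortExperiment:
    inten = _read_tsv_matrix(matrix_path)
    lab = pd.read_csv(labels_path, sep="\t", index_col=0, dtype=str)
    labels = lab.iloc[:, 0]
    labels.index = labels.index.astype(str)
    return CohortExperiment(inten, labels, name=name)


def write_cohort(cohort: CohortExperiment, out_dir: str | Path, prefix: str) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}_intensities.tsv",
        "labels": out / f"{prefix}_labels.tsv",
    }
    cohort.intensities.to_csv(paths["matrix"], sep="\t", index_label="gene_id", na_rep=MISSING)
    cohort.labels.rename("group").to_csv(paths["labels"], sep="\t", index_label="sample_id")
    return paths


# ---------------------------------------------------------------------------
# genomic intervals (BED, 0-based half-open)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A named 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"{self.name}: negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start})"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 4+ column BED file into validated intervals, order preserved."""
    intervals: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns (name required)")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
    return path


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: unique member list}``.

    Duplicate members within a set are deduplicated (first occurrence wins)
    with a logged warning; duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >= 1 member")
            name, _desc, *members = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < len([m for m in members if m]):
                logger.warning("gene set %s: duplicate members deduplicated", name)
            sets[name] = unique
    if not sets:
        raise ValidationError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, MISSING, *members]) + "\n")
    return path


# ---------------------------------------------------------------------------
# ortholog table
# ---------------------------------------------------------------------------


@dataclass
class OrthologTable:
    """Source-gene -> target-symbol map (e.g. rat probe -> human symbol).

    A source gene maps to at most one target symbol; rows beyond the first
    for a source are dropped and reported in ``dropped``, not raised — the
    common many-to-many reality of cross-platform annotation.
    """

    mapping: dict[str, str]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValidationError("ortholog table is empty")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "OrthologTable":
        mapping: dict[str, str] = {}
        dropped: list[tuple[str, str]] = []
        seen_rows: set[tuple[str, str]] = set()
        for src, tgt in rows:
            row = (src, tgt)
            if row in seen_rows:
                raise ValidationError(f"duplicated ortholog row: {row}")
            seen_rows.add(row)
            if src in mapping:
                dropped.append(row)
            else:
                mapping[src] = tgt
        if dropped:
            logger.warning("ortholog table: %d multi-mapping rows dropped", len(dropped))
        return cls(mapping, dropped)

    @property
    def targets(self) -> set[str]:
        return set(self.mapping.values())

    def __len__(self) -> int:
        return len(self.mapping)


def read_ortholog_table(path: str | Path) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog table needs 2 columns (source, target)")
    return OrthologTable.from_rows(
        (str(r), str(t)) for r, t in zip(df.iloc[:, 0], df.iloc[:, 1])
    )


def write_ortholog_table(table: OrthologTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        sorted(table.mapping.items()), columns=["source_gene_id", "target_gene_symbol"]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

CT_COLUMNS = ["gene", "sample", "group", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-form qPCR cycle-threshold table (triplicates as separate rows)."""

    table: pd.DataFrame  # columns: gene, sample, group, replicate, ct
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.table.columns)
        if missing:
            raise StructuralError(f"Ct table lacks columns {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown Ct group label(s): {sorted(bad)}")
        ref_samples = set(
            self.table.loc[self.table["gene"] == self.reference_gene, "sample"]
        )
        all_samples = set(self.table["sample"])
        if ref_samples != all_samples:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} missing in "
                f"{len(all_samples - ref_samples)} sample(s)"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.table["gene"]))


def read_ct_table(path: str | Path, reference_gene: str = "GAPDH") -> CtTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str, "group": str})
    return CtTable(df, reference_gene=reference_gene)


def write_ct_table(ct: CtTable, path: str | Path) -> Path:
    path = Path(path)
    ct.table[CT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# results bundle + manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results_bundle(
    results: Mapping[str, str],
    out_dir: str | Path,
    config: Mapping | None = None,
    failed_stage: str | None = None,
) -> dict:
    """Write named text artifacts plus a config echo and a checksum manifest.

    ``results`` maps relative file names to already-serialized text content,
    so the same results always produce byte-identical files (and therefore
    identical checksums — the pipeline's determinism contract).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    for name, content in results.items():
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(content, encoding="utf-8")
        written.append(path)
    config_path = out / "run_config.yaml"
    config_path.write_text(
        yaml.safe_dump(dict(config or {}), sort_keys=True), encoding="utf-8"
    )
    written.append(config_path)
    manifest = {
        "files": {p.relative_to(out).as_posix(): _sha256(p) for p in sorted(written)},
        "status": "FAILED" if failed_stage else "OK",
    }
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
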