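"""Genotype, phenotype and tabular artifact I/O.

Genotypes are held as a sample x variant matrix of effect-allele counts
(0, 1, 2) with ``NaN`` marking missing calls.  Two on-disk dialects are
supported: VCF v4.2 (only the GT subfield is consulted; biallelic SNPs
only) and a plain genotype TSV whose header row is ``sample_id`` followed
by variant identifiers, with cells in {0, 1, 2, NA}.  Because the genotype
TSV carries no positional or allele metadata, every writer emits a sidecar
``<name>.variants.tsv`` describing each column; the reader picks it up
automatically so that write -> read round-trips losslessly.

Phenotype tables are plain TSV with one row per subject: BCR event
indicator, follow-up in months, and the standard post-prostatectomy
clinicopathological covariates (age, PSA, prostate volume, Gleason score,
extracapsular extension, seminal vesicle invasion, bladder-neck invasion,
surgical-margin status, pathological T stage).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .errors import (
    AlignmentError,
    DuplicateVariantError,
    UnsupportedRecordError,
    ValidationError,
    VcfParseError,
)

MISSING = np.nan

_BASES = frozenset("ACGT")

PHENOTYPE_COLUMNS = [
    "sample_id",
    "bcr_event",
    "followup_months",
    "age_years",
    "psa_ng_ml",
    "prostate_volume_ml",
    "gleason",
    "ece",
    "svi",
    "bni",
    "psm",
    "pt_stage",
]

PT_STAGES = ("pT2", "pT3", "pT4")


@dataclass(frozen=True)
class VariantRecord:
    """Identity of one biallelic SNP.

    ``effect_allele`` is the counted allele (the cohort minor allele once the
    association stage has oriented it); ``other_allele`` is its partner.
    ``gene`` may be empty for intergenic markers.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    gene: str = ""

    def __post_init__(self):
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise ValidationError(
                f"{self.variant_id}: alleles must be single bases, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: alleles must differ")
        if self.position < 1:
            raise ValidationError(f"{self.variant_id}: position must be 1-based")


@dataclass
class GenotypeMatrix:
    """Sample x variant matrix of effect-allele counts with NaN as missing."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    counts: np.ndarray  # float64, shape (n_samples, n_variants)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"genotype count {bad!r} outside {{0,1,2,NA}}")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateVariantError(f"duplicated variant ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(variant_id) from None

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        """Return a new matrix restricted by boolean masks (None keeps all)."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vmask = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask, bool)
        return GenotypeMatrix(
            [s for s, k in zip(self.sample_ids, smask) if k],
            [v for v, k in zip(self.variants, vmask) if k],
            self.counts[np.ix_(smask, vmask)].copy(),
        )

    def flip_variant(self, index: int) -> None:
        """Swap effect/other allele of one variant and recode counts as 2 - g."""
        v = self.variants[index]
        self.variants[index] = replace(
            v, effect_allele=v.other_allele, other_allele=v.effect_allele
        )
        self.counts[:, index] = 2.0 - self.counts[:, index]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.counts, other.counts, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a GenotypeMatrix.

    Counts are the number of ALT alleles in the GT field; the effect allele is
    ALT.  Any missing or half-missing call (``./.``, ``0/.``) becomes NaN.
    Multiallelic or non-SNP records are collected and rejected together.
    """
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(str(exc)) from exc
    sample_ids = list(vcf.header.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    bad: list[str] = []
    seen: set[str] = set()
    with vcf:
        for lineno, rec in enumerate(vcf, start=1):
            name = rec.id or f"{rec.chrom}:{rec.pos}"
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in _BASES
                or alts[0] not in _BASES
            ):
                bad.append(name)
                continue
            if name in seen:
                raise DuplicateVariantError(f"duplicated variant id {name!r}")
            seen.add(name)
            row = np.full(len(sample_ids), MISSING)
            for i, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    continue  # half-calls and no-calls stay missing
                if any(a not in (0, 1) for a in gt):
                    raise VcfParseError(
                        f"{name}: GT allele index outside biallelic range", line=lineno
                    )
                row[i] = float(sum(gt))
            variants.append(
                VariantRecord(
                    variant_id=name,
                    chromosome=str(rec.chrom),
                    position=int(rec.pos),
                    effect_allele=alts[0],
                    other_allele=rec.ref,
                )
            )
            rows.append(row)
    if bad:
        raise UnsupportedRecordError(bad)
    counts = np.vstack(rows).T if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, variants, counts)


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns.

    The effect allele is written as ALT and the other allele as REF, so that
    ``read_vcf(write_vcf(x))`` restores the same counts.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chromosome for v in genotypes.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in enumerate(genotypes.variants):
            col = genotypes.counts[:, j]
            calls = "\t".join(
                "./." if np.isnan(g) else gt_strings[g] for g in col
            )
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.variant_id}\t"
                f"{v.other_allele}\t{v.effect_allele}\t.\t.\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Genotype TSV dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    base, ext = os.path.splitext(path)
    return base + ".variants" + (ext or ".tsv")


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write counts as TSV (header ``sample_id`` + variant ids, cells 0/1/2/NA)
    plus a ``.variants.tsv`` sidecar holding each column's metadata."""
    path = os.fspath(path)
    body = pd.DataFrame(
        genotypes.counts, index=genotypes.sample_ids, columns=genotypes.variant_ids
    )
    body = body.map(lambda x: "NA" if np.isnan(x) else str(int(x)))
    body.index.name = "sample_id"
    body.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        [
            (v.variant_id, v.chromosome, v.position, v.effect_allele, v.other_allele, v.gene or ".")
            for v in genotypes.variants
        ],
        columns=["variant_id", "chromosome", "position", "effect_allele", "other_allele", "gene"],
    )
    meta.to_csv(_sidecar_path(path), sep="\t", index=False)


def read_genotype_tsv(
    path: str | os.PathLike, variants_path: str | os.PathLike | None = None
) -> GenotypeMatrix:
    """Read the genotype TSV dialect.

    Variant metadata comes from ``variants_path`` (default: the ``.variants.tsv``
    sidecar next to ``path``).  Without a sidecar, placeholder records with
    unknown chromosome and A/G alleles are synthesized so that purely
    count-based operations still work.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValidationError(
            f"{path}: first header column must be 'sample_id', got {df.columns[0]!r}"
        )
    variant_ids = list(df.columns[1:])
    sample_ids = df["sample_id"].astype(str).tolist()
    counts = np.full((len(sample_ids), len(variant_ids)), MISSING)
    for j, vid in enumerate(variant_ids):
        for i, cell in enumerate(df[vid]):
            cell = "NA" if pd.isna(cell) else str(cell).strip()
            if cell == "NA":
                continue
            if cell not in ("0", "1", "2"):
                raise ValidationError(
                    f"{path}: cell ({sample_ids[i]}, {vid}) = {cell!r} outside {{0,1,2,NA}}"
                )
            counts[i, j] = float(cell)

    if variants_path is None and os.path.exists(_sidecar_path(path)):
        variants_path = _sidecar_path(path)
    if variants_path is not None:
        meta = pd.read_csv(variants_path, sep="\t", dtype=str)
        records = {
            row.variant_id: VariantRecord(
                variant_id=row.variant_id,
                chromosome=str(row.chromosome),
                position=int(row.position),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                gene="" if row.gene in (".", "", None) else row.gene,
            )
            for row in meta.itertuples()
        }
        missing = [vid for vid in variant_ids if vid not in records]
        if missing:
            raise ValidationError(f"variant metadata missing for: {missing}")
        variants = [records[vid] for vid in variant_ids]
    else:
        variants = [
            VariantRecord(vid, chromosome="0", position=j + 1, effect_allele="A", other_allele="G")
            for j, vid in enumerate(variant_ids)
        ]
    return GenotypeMatrix(sample_ids, variants, counts)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Type-check and range-check a phenotype table; returns a typed copy."""
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns and c != "prostate_volume_ml"]
    if missing_cols:
        raise ValidationError(f"phenotype table missing columns: {missing_cols}")
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        raise ValidationError("duplicated sample_id in phenotype table")
    core = out[["bcr_event", "followup_months"]]
    if core.isna().any().any():
        bad = out.loc[core.isna().any(axis=1), "sample_id"].tolist()
        raise ValidationError(f"missing bcr_event/followup_months for samples {bad}")
    out["bcr_event"] = out["bcr_event"].astype(int)
    if not out["bcr_event"].isin((0, 1)).all():
        raise ValidationError("bcr_event must be 0 or 1")
    out["followup_months"] = out["followup_months"].astype(float)
    if (out["followup_months"] <= 0).any():
        bad = out.loc[out["followup_months"] <= 0, "sample_id"].tolist()
        raise ValidationError(f"followup_months must be > 0; offending samples {bad}")
    out["age_years"] = out["age_years"].astype(float)
    for col in ("psa_ng_ml", "prostate_volume_ml"):
        if col in out.columns:
            out[col] = out[col].astype(float)
            if (out[col].dropna() < 0).any():
                raise ValidationError(f"{col} must be nonnegative")
    out["gleason"] = out["gleason"].astype(int)
    if not out["gleason"].between(6, 10).all():
        bad = out.loc[~out["gleason"].between(6, 10), "sample_id"].tolist()
        raise ValidationError(f"gleason must be in 6..10; offending samples {bad}")
    for col in ("ece", "svi", "bni", "psm"):
        out[col] = out[col].astype(int)
        if not out[col].isin((0, 1)).all():
            raise ValidationError(f"{col} must be binary")
    out["pt_stage"] = out["pt_stage"].astype(str)
    if not out["pt_stage"].isin(PT_STAGES).all():
        bad = sorted(set(out.loc[~out["pt_stage"].isin(PT_STAGES), "pt_stage"]))
        raise ValidationError(f"unknown pt_stage values: {bad}")
    return out.reset_index(drop=True)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_phenotypes(df).to_csv(path, sep="\t", index=False)


def align_samples(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Return phenotypes reordered to the genotype sample order; error on mismatch."""
    pheno_ids = set(phenotypes["sample_id"])
    geno_ids = set(genotypes.sample_ids)
    if pheno_ids != geno_ids:
        raise AlignmentError(
            f"sample sets differ: {len(geno_ids - pheno_ids)} genotype-only, "
            f"{len(pheno_ids - geno_ids)} phenotype-only"
        )
    return (
        phenotypes.set_index("sample_id")
        .loc[genotypes.sample_ids]
        .reset_index()
    )
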