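"""Readers and writers for the formats the pipeline touches.

Genotypes come from VCF (DS dosage field when present, otherwise GT allele
counts), PLINK bed/bim/fam, or a plain TSV dialect; phenotypes, expression,
annotation and term-membership tables are TSV (tab-separated, header row,
``.`` for missing).  Annotation is also accepted as GFF3 or BED.  All
coordinates are 1-based; a coordinate of 0 is rejected.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
)

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation_tsv",
    "read_term_membership",
]


class ParseError(ValueError):
    """Raised for malformed records; message names the offending line."""


def read_genotypes(path: str | os.PathLike, format: str | None = None) -> GenotypeMatrix:
    """Load a dosage panel from VCF, PLINK bed/bim/fam, or the TSV dialect.

    ``format`` is one of ``vcf``, ``plink``, ``tsv``; when omitted it is
    inferred from the file suffix (``.vcf``/``.vcf.gz``, ``.bed``, ``.tsv``).
    """
    path = Path(path)
    if format is None:
        name = path.name
        if name.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif name.endswith(".bed"):
            format = "plink"
        elif name.endswith(".tsv"):
            format = "tsv"
        else:
            raise ValueError(f"cannot infer genotype format from {name!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        if rec.POS < 1:
            raise ParseError(f"{path}: coordinate {rec.POS} at {rec.CHROM} is not 1-based")
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{path}: variant {rec.ID or rec.POS} is not biallelic"
            )
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=np.float64).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 hom-alt (cyvcf2 gt_types uses 3 for hom-alt)
            gts = rec.genotype.array()[:, :2]
            if (gts < 0).any():
                raise ParseError(
                    f"{path}: missing GT at {rec.CHROM}:{rec.POS} (no DS fallback)"
                )
            dos = gts.sum(axis=1).astype(np.float64)
        if dos.min() < 0 or dos.max() > 2:
            raise ValidationError(
                f"{path}: dosage outside [0,2] at {rec.CHROM}:{rec.POS}"
            )
        rows.append(dos)
        r2 = rec.INFO.get("R2")
        cols.append(
            (rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}", rec.REF,
             rec.ALT[0], np.nan if r2 is None else float(r2))
        )
    variants = pd.DataFrame(cols, columns=["chrom", "pos", "id", "ref", "alt", "imp_r2"])
    return GenotypeMatrix(samples, variants, np.array(rows).T if rows else np.empty((len(samples), 0)))


def _read_plink(bed_path: Path) -> GenotypeMatrix:
    """Minimal PLINK 1 bed/bim/fam reader (SNP-major, 2-bit encoding)."""
    stem = bed_path.with_suffix("")
    fam = pd.read_csv(stem.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(
        stem.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    if (bim["pos"] < 1).any():
        raise ParseError(f"{bed_path}: 0-based coordinate in .bim")
    samples = fam[1].astype(str).tolist()
    n, m = len(samples), len(bim)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ParseError(f"{bed_path}: not a SNP-major PLINK .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit codes: 00 hom a1(=2 copies of a1), 01 missing, 10 het, 11 hom a2
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])  # a1 counted as the dosage allele
    dosages = lut[codes].T
    if np.isnan(dosages).any():
        raise ValidationError(f"{bed_path}: missing genotypes are not supported")
    variants = bim.assign(imp_r2=np.nan)[["chrom", "pos", "id", "a1", "a2", "imp_r2"]]
    variants.columns = ["chrom", "pos", "id", "ref", "alt", "imp_r2"]
    # PLINK counts a1 (usually the minor allele); keep that convention as alt
    variants = variants.rename(columns={"ref": "alt", "alt": "ref"})[
        ["chrom", "pos", "id", "ref", "alt", "imp_r2"]
    ]
    return GenotypeMatrix(samples, variants, dosages)


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(
        path, sep="\t", na_values=["."], dtype={"chrom": str},
        float_precision="round_trip",
    )
    meta_cols = ["chrom", "pos", "id", "ref", "alt", "imp_r2"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if (df["pos"] < 1).any():
        line = int(np.flatnonzero(df["pos"].to_numpy() < 1)[0]) + 2
        raise ParseError(f"{path}: 0-based coordinate at line {line}")
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=np.float64).T
    return GenotypeMatrix(samples, df[meta_cols], dosages)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Serialize the panel to the TSV dialect at full float precision."""
    dos = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    df = pd.concat([g.variants.reset_index(drop=True), dos], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")


def read_phenotypes(
    path: str | os.PathLike,
    trait_columns: list[str] | None = None,
    categorical: list[str] | None = None,
) -> PhenotypeTable:
    """Read a sample-indexed TSV of traits and covariates.

    First column is the sample id.  Columns are traits unless listed in
    ``categorical`` or non-numeric; pass ``trait_columns`` to be explicit.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."], index_col=0)
    df.index = df.index.astype(str)
    categorical = list(categorical or [])
    if trait_columns is None:
        trait_columns = [
            c for c in df.columns
            if c not in categorical and pd.api.types.is_numeric_dtype(df[c])
        ]
    cov_cols = [c for c in df.columns if c not in trait_columns]
    return PhenotypeTable(
        traits=df[trait_columns].astype(float),
        covariates=df[cov_cols],
        categorical=[c for c in categorical if c in cov_cols],
    )


def write_phenotypes(p: PhenotypeTable, path: str | os.PathLike) -> None:
    pd.concat([p.traits, p.covariates], axis=1).to_csv(
        path, sep="\t", na_rep=".", index_label="sample_id"
    )


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Gene x sample TSV; first column gene id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", na_values=["."], index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression(e: ExpressionMatrix, path: str | os.PathLike) -> None:
    e.values.to_csv(path, sep="\t", na_rep=".", index_label="gene_id")


def read_annotation(path: str | os.PathLike, format: str | None = None) -> GeneAnnotation:
    """Gene annotation from GFF3, BED, or a TSV with explicit columns."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".gff3": "gff3", ".gff": "gff3", ".bed": "bed", ".tsv": "tsv"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed":
        return _read_bed(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return GeneAnnotation(df[["gene_id", "chrom", "start", "end", "strand"]])
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path: Path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            if int(start) < 1:
                raise ParseError(f"{path}: line {lineno}: 0-based coordinate")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}: line {lineno}: gene without ID attribute")
            rows.append((gid, chrom, int(start), int(end),
                         strand if strand in "+-" else "unknown"))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def _read_bed(path: Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ParseError(f"{path}: BED needs >= 4 columns (chrom, start, end, name)")
    strand = df[5] if df.shape[1] >= 6 else "unknown"
    out = pd.DataFrame(
        {
            "gene_id": df[3].astype(str),
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,  # BED is 0-based half-open
            "end": df[2].astype(int),
            "strand": strand,
        }
    )
    if (df[1] < 0).any():
        raise ParseError(f"{path}: negative BED start")
    return GeneAnnotation(out)


def write_annotation_tsv(ann: GeneAnnotation, path: str | os.PathLike) -> None:
    ann.table[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False
    )


def read_term_membership(path: str | os.PathLike) -> pd.DataFrame:
    """Two-column TSV ``gene_id<TAB>term`` mapping genes to ontology terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "term"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: membership TSV needs columns {sorted(need)}")
    return df[["gene_id", "term"]]
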