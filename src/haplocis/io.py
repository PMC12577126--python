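"""Readers and writers for the interchange formats shared by every stage.

Internal convention is 0-based half-open coordinates; conversion happens only
at file boundaries (GFF3 is 1-based closed, BED 0-based half-open, VCF
1-based). All writers produce plain text; gzip input is handled transparently
by the underlying libraries where they support it.
"""
from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .config import ASSAYS


class FormatError(ValueError):
    """A file violates its declared schema."""


VARIANT_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt",
    "hap1_allele", "hap2_allele", "block_id", "informative",
    "hap1_parent_call",
]

COUNT_COLUMNS = ["snp_id", "chrom", "pos", "block_id", "hap1_count", "hap2_count"]


@dataclass
class VcfLoadReport:
    n_loaded: int
    n_skipped_unphased: int
    n_skipped_multiallelic: int
    n_skipped_homozygous: int


def _opener(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf_phased(variants: pd.DataFrame, path, chrom_sizes: dict[str, int]) -> None:
    """Write phased heterozygous variants as a VCF 4.2 file.

    ``variants`` uses internal 0-based positions; VCF POS is written 1-based.
    The phase block id goes into the PS FORMAT tag and GT is phased
    (hap1|hap2 in allele indices).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for row in variants.itertuples(index=False):
            a1 = 0 if row.hap1_allele == row.ref else 1
            a2 = 0 if row.hap2_allele == row.ref else 1
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT:PS\t{a1}|{a2}:{row.block_id}\n"
            )


def read_vcf_phased(path) -> tuple[pd.DataFrame, VcfLoadReport]:
    """Load biallelic phased heterozygous records carrying a PS tag.

    Returns the variant table (internal 0-based positions) and a report of
    skipped records. Unphased heterozygotes and multiallelic or homozygous
    records are counted, not loaded.
    """
    rows = []
    n_unphased = n_multi = n_hom = 0
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = rec.genotypes[0]  # [a1, a2, phased]
        a1, a2, phased = gt[0], gt[1], gt[2]
        if a1 == a2:
            n_hom += 1
            continue
        if not phased:
            n_unphased += 1
            continue
        ps = rec.format("PS")
        block_id = int(ps[0][0]) if ps is not None else -1
        if block_id < 0:
            n_unphased += 1
            continue
        alleles = [rec.REF, rec.ALT[0]]
        rows.append(
            (
                rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}",
                rec.CHROM,
                rec.POS - 1,
                rec.REF,
                rec.ALT[0],
                alleles[a1],
                alleles[a2],
                block_id,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "ref", "alt", "hap1_allele",
                 "hap2_allele", "block_id"],
    )
    report = VcfLoadReport(len(df), n_unphased, n_multi, n_hom)
    return df, report


def write_parental_vcf(variants: pd.DataFrame, path, chrom_sizes: dict[str, int]) -> None:
    """Write parental genotypes for ancestry-informative SNPs.

    Informative SNPs are homozygous for alternate alleles in the two parents:
    the maternal sample is homozygous for the maternal allele and vice versa.
    """
    inf = variants[variants["informative"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmaternal\tpaternal\n")
        for row in inf.itertuples(index=False):
            mat_allele = (
                row.hap1_allele if row.hap1_parent_call == "maternal" else row.hap2_allele
            )
            m = "0/0" if mat_allele == row.ref else "1/1"
            p = "1/1" if m == "0/0" else "0/0"
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{m}\t{p}\n"
            )


# ---------------------------------------------------------------------------
# Intervals: BED and GFF3
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, name_col: str = "name",
              score_col: str | None = None, strand_col: str | None = None) -> None:
    """Write a BED6-style file from a frame with chrom/start/end columns."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            d = row._asdict()
            name = d.get(name_col, ".")
            score = d.get(score_col, 0) if score_col else 0
            strand = d.get(strand_col, ".") if strand_col else "."
            fh.write(f"{d['chrom']}\t{d['start']}\t{d['end']}\t{name}\t{score}\t{strand}\n")


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models as GFF3 (1-based closed on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\thaplocis\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_intervals(path, dialect: str) -> pd.DataFrame:
    """Read BED or GFF3 into the internal 0-based half-open convention.

    Records whose converted span is empty or negative are rejected with their
    line number.
    """
    if dialect == "BED":
        rows = []
        with _opener(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start < 0:
                    raise FormatError(f"{path}:{lineno}: negative coordinate")
                if start >= end:
                    raise FormatError(f"{path}:{lineno}: empty interval {start}>={end}")
                name = parts[3] if len(parts) > 3 else "."
                score = parts[4] if len(parts) > 4 else "0"
                strand = parts[5] if len(parts) > 5 else "."
                rows.append((chrom, start, end, name, score, strand))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if dialect == "GFF3":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for feat in db.all_features():
            start = feat.start - 1  # GFF3 1-based closed -> half-open
            end = feat.end
            if start < 0 or start >= end:
                raise FormatError(f"{path}: feature {feat.id}: bad span {feat.start}..{feat.end}")
            name = feat.attributes.get("ID", [feat.id])[0]
            rows.append((feat.seqid, start, end, name, ".", feat.strand or "."))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    raise ValueError(f"unknown dialect {dialect!r}")


def read_genes_gff3(path) -> pd.DataFrame:
    df = read_intervals(path, "GFF3")
    return df.rename(columns={"name": "gene_id"})[
        ["gene_id", "chrom", "start", "end", "strand"]
    ]


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def write_counts(df: pd.DataFrame, path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_counts(path, assay: str, known_snp_ids=None) -> pd.DataFrame:
    """Load and validate one per-assay allelic count table.

    Checks: the assay name is in the registry, counts are non-negative
    integers, (snp_id) keys are unique, and — when a variant set is supplied —
    every snp_id resolves against it.
    """
    if assay not in ASSAYS:
        raise FormatError(f"unknown assay {assay!r}; registry: {ASSAYS}")
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("hap1_count", "hap2_count"):
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError(f"{path}: column {col} is not integer")
        bad = np.nonzero(vals < 0)[0]
        if len(bad):
            raise FormatError(f"{path}: negative count at data row {bad[0] + 1}")
    dup = df["snp_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate snp_id {df.loc[dup.idxmax(), 'snp_id']!r}"
        )
    if known_snp_ids is not None:
        unknown = set(df["snp_id"]) - set(known_snp_ids)
        if unknown:
            raise FormatError(f"{path}: {len(unknown)} snp_ids not in variant set")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
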