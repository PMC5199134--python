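"""Readers and writers for the standard formats the selector touches.

Tab-separated matrices (features as rows, FANTOM convention; a GCT
dialect covers GTEx median-expression tables), BED3/4/6 intervals with
an optional UCSC custom-track header, genome FASTA slicing with flanks,
VCF or 3-column TSV SNP positions, and the small annotation tables
(genes, facet maps, enhancer-promoter associations, ordinal protein
levels).  VCF and dbSNP positions are 1-based and converted to 0-based
on ingest; everything written out is BED-convention 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import pyfaidx
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExpressionMatrix, FacetMap, validate_matrix
from .constraints import ORDINAL_LEVELS
from .errors import (
    FormatError,
    UnknownChromosomeError,
    ValidationError,
)
from .genomic import AssociationRecord, GeneRecord, GenomicFeature, SNPRecord


@dataclass(frozen=True)
class TrackSpec:
    """UCSC custom-track header attributes for a BED export."""

    track_name: str
    description: str = ""
    color: tuple[int, int, int] = (0, 0, 0)
    visibility: str = "dense"

    def __post_init__(self):
        if not self.track_name or "\t" in self.track_name:
            raise ValidationError("track name must be non-empty and tab-free")

    def header_line(self) -> str:
        name = self.track_name if " " not in self.track_name else f'"{self.track_name}"'
        r, g, b = self.color
        return (
            f"track name={name} description=\"{self.description}\" "
            f"color={r},{g},{b} visibility={self.visibility}"
        )


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_table(
    path: str | os.PathLike,
    missing_policy: Literal["zero", "error"] = "error",
    unit: str = "arbitrary",
    transpose: bool = False,
    dialect: Literal["tsv", "gct"] = "tsv",
) -> ExpressionMatrix:
    """Read a feature x sample TSV matrix (first column = feature ids).

    ``dialect="gct"`` skips the 2-line GCT preamble and drops the
    Description column, covering GTEx median-expression downloads.
    ``transpose=True`` reads column-major (samples-as-rows) sources.
    Missing cells become 0 under policy "zero" and are rejected under
    "error" (the default — silent zero fabrication is opt-in).
    """
    skiprows = 2 if dialect == "gct" else 0
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows,
                         float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"cannot parse expression table {path}: {exc}") from exc
    if dialect == "gct" and len(df.columns) and df.columns[0].lower() == "description":
        df = df.drop(columns=df.columns[0])
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate non-numeric cells precisely before letting the matrix validate
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = next(zip(*bad.to_numpy().nonzero()))
        raise FormatError(
            f"non-numeric value {df.iat[i, j]!r} at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        if missing_policy == "zero":
            numeric = numeric.fillna(0.0)
        else:
            i, j = next(zip(*numeric.isna().to_numpy().nonzero()))
            raise FormatError(
                f"missing value at feature {numeric.index[i]!r}, "
                f"sample {numeric.columns[j]!r} (policy 'error')"
            )
    numeric.index.name = None
    numeric.columns.name = None
    findings = [f for f in validate_matrix(numeric) if f.kind == "duplicate id"]
    if findings:
        raise ValidationError(f"{findings[0].kind}: {findings[0].subject!r}")
    return ExpressionMatrix(numeric.astype(float), unit=unit)


def write_expression_table(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    # %.17g round-trips float64 exactly
    matrix.values.to_csv(path, sep="\t", index_label="feature_id",
                         float_format="%.17g")


def write_contribution_table(contrib, path: str | os.PathLike) -> None:
    """Write a percentage table; undefined rows are written as zeros."""
    contrib.percentages.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> list[GenomicFeature]:
    """Read BED3/4/6; track/browser/comment lines are skipped.

    Features without a name column are named ``<chrom>:<start>-<end>``.
    """
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED line has fewer than 3 columns", line=lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"non-integer coordinates {parts[1]!r}/{parts[2]!r}", line=lineno
                ) from None
            if start >= end:
                raise FormatError(f"start {start} >= end {end}", line=lineno)
            name = parts[3] if len(parts) > 3 and parts[3] else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            try:
                feats.append(GenomicFeature(name, chrom, start, end, strand))
            except ValidationError as exc:
                raise FormatError(str(exc), line=lineno) from exc
    return feats


def write_bed(
    features: Iterable[GenomicFeature],
    path: str | os.PathLike,
    track: TrackSpec | None = None,
) -> None:
    """Write BED6 (name, score 0, strand), optionally under a track header."""
    with open(path, "w") as fh:
        if track is not None:
            fh.write(track.header_line() + "\n")
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# FASTA extraction


def extract_fasta(
    features: Iterable[GenomicFeature],
    genome_fasta_path: str | os.PathLike,
    flank_bp: int = 0,
) -> list[SeqRecord]:
    """Slice each feature (plus symmetric flanks) out of a genome FASTA.

    Coordinates are clamped to [0, chromosome length); the record id is
    ``feature_id::chrom:start-end`` with the clamped 0-based half-open
    coordinates and the strand in the description.  Sequence case is
    preserved and nothing is reverse-complemented.
    """
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    genome = pyfaidx.Fasta(str(genome_fasta_path), as_raw=True)
    records: list[SeqRecord] = []
    for f in features:
        if f.chrom not in genome:
            raise UnknownChromosomeError(
                f"chromosome {f.chrom!r} not present in {genome_fasta_path}"
            )
        chrom_len = len(genome[f.chrom])
        start = max(0, f.start - flank_bp)
        end = min(chrom_len, f.end + flank_bp)
        seq = str(genome[f.chrom][start:end])
        records.append(
            SeqRecord(
                Seq(seq),
                id=f"{f.feature_id}::{f.chrom}:{start}-{end}",
                description=f"strand={f.strand}",
            )
        )
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | os.PathLike) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# small annotation tables

def _data_lines(path, n_cols: int, what: str):
    """Yield (lineno, fields) for non-comment lines, tolerating a header row."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < n_cols:
                raise FormatError(
                    f"{what}: expected {n_cols} tab-separated columns", line=lineno
                )
            yield lineno, parts


def read_gene_table(path: str | os.PathLike) -> list[GeneRecord]:
    """Read gene annotation: symbol / chrom / tss (0-based) / strand.

    A gene may appear on several lines (one per annotated TSS).
    """
    genes: list[GeneRecord] = []
    for lineno, parts in _data_lines(path, 4, "gene table"):
        symbol, chrom, tss_s, strand = parts[:4]
        try:
            tss = int(tss_s)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise FormatError(f"non-integer TSS {tss_s!r}", line=lineno) from None
        try:
            genes.append(GeneRecord(symbol, chrom, tss, strand))
        except ValidationError as exc:
            raise FormatError(str(exc), line=lineno) from exc
    return genes


def read_snp_table(
    path: str | os.PathLike, format: Literal["vcf", "tsv"] = "tsv"
) -> list[SNPRecord]:
    """Read SNP positions from a VCF or an id/chrom/pos(1-based) TSV.

    Only positions are kept; a multi-allelic VCF record yields one
    SNPRecord.  Both sources are 1-based and converted to 0-based.
    """
    snps: list[SNPRecord] = []
    if format == "vcf":
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                snp_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
                snps.append(SNPRecord(snp_id, rec.chrom, rec.start))  # rec.start is 0-based
        return snps
    if format != "tsv":
        raise FormatError(f"unknown SNP table format {format!r}")
    for lineno, parts in _data_lines(path, 3, "SNP table"):
        snp_id, chrom, pos_s = parts[:3]
        try:
            pos1 = int(pos_s)
        except ValueError:
            if lineno == 1:
                continue
            raise FormatError(f"non-integer position {pos_s!r}", line=lineno) from None
        if pos1 < 1:
            raise FormatError(f"1-based position must be >= 1, got {pos1}", line=lineno)
        snps.append(SNPRecord(snp_id, chrom, pos1 - 1))
    return snps


def read_association_table(path: str | os.PathLike) -> list[AssociationRecord]:
    """Read enhancer / promoter / correlation-score associations (TSV)."""
    recs: list[AssociationRecord] = []
    for lineno, parts in _data_lines(path, 3, "association table"):
        enh, prom, score_s = parts[:3]
        try:
            score = float(score_s)
        except ValueError:
            if lineno == 1:
                continue
            raise FormatError(f"non-numeric score {score_s!r}", line=lineno) from None
        try:
            recs.append(AssociationRecord(enh, prom, score))
        except ValidationError as exc:
            raise FormatError(str(exc), line=lineno) from exc
    return recs


def read_facet_map(path: str | os.PathLike) -> dict[str, FacetMap]:
    """Read a sample / facet / panel TSV into one FacetMap per panel.

    Facet order within a panel is first-appearance order.
    """
    per_panel: dict[str, dict[str, str]] = {}
    order: dict[str, list[str]] = {}
    first = True
    for lineno, parts in _data_lines(path, 3, "facet map"):
        sample, facet, panel = parts[:3]
        if first and (sample.lower(), facet.lower(), panel.lower()) == (
            "sample", "facet", "panel",
        ):
            first = False
            continue
        first = False
        mapping = per_panel.setdefault(panel, {})
        if sample in mapping:
            raise FormatError(
                f"sample {sample!r} mapped twice in panel {panel!r}", line=lineno
            )
        mapping[sample] = facet
        facets = order.setdefault(panel, [])
        if facet not in facets:
            facets.append(facet)
    return {
        panel: FacetMap(panel, mapping, tuple(order[panel]))
        for panel, mapping in per_panel.items()
    }


def read_ordinal_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene / tissue / level long-format TSV to a gene x tissue table.

    Levels must come from the four-step staining scale; unrecorded
    gene/tissue pairs are NA.  Unknown labels are a parse error.
    """
    rows: list[tuple[str, str, str]] = []
    for lineno, parts in _data_lines(path, 3, "ordinal table"):
        gene, tissue, level = parts[:3]
        if lineno == 1 and (gene.lower(), level.lower()) in (
            ("gene", "level"), ("gene", "value"),
        ):
            continue
        if level not in ORDINAL_LEVELS:
            raise FormatError(
                f"unknown protein level {level!r}; expected one of {ORDINAL_LEVELS}",
                line=lineno,
            )
        rows.append((gene, tissue, level))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["gene", "tissue", "level"])
    wide = df.pivot_table(
        index="gene", columns="tissue", values="level", aggfunc="first"
    )
    wide.index.name = None
    wide.columns.name = None
    # preserve first-appearance order of genes and tissues
    gene_order = list(dict.fromkeys(df["gene"]))
    tissue_order = list(dict.fromkeys(df["tissue"]))
    return wide.reindex(index=gene_order, columns=tissue_order)


def write_pairs(
    pairs: Iterable[tuple[str, str]], path: str | os.PathLike,
    header: tuple[str, str] = ("enhancer_id", "snp_id"),
) -> None:
    """Write (id, id) pairs as sorted two-column TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")
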