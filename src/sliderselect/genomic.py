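"""Location-based selection and enhancer-SNP / enhancer-promoter annotation.

All coordinates are 0-based half-open (BED convention); 1-based sources
(VCF, dbSNP) are converted at read time.  The SNP overlap rule is the
midpoint rule: an enhancer and a SNP are reported as a pair when they
lie on the same chromosome and the distance between the enhancer
midpoint and the SNP position is at most ``max_dist`` (default 200 bp).
Even-length intervals take the floor midpoint, floor((start + end) / 2).
"""

from __future__ import annotations

import difflib
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np

from .errors import UnknownGeneError, ValidationError

#: default half-width of the gene TSS window (bp)
DEFAULT_GENE_WINDOW = 100_000
#: default maximum enhancer-midpoint-to-SNP distance (bp)
DEFAULT_SNP_MAX_DIST = 200


@dataclass(frozen=True)
class GenomicFeature:
    """A named interval in 0-based half-open coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError(f"feature {self.feature_id!r}: empty chromosome")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(
                f"feature {self.feature_id!r}: invalid strand {self.strand!r}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def anchor(self, kind: Literal["midpoint", "start5"] = "midpoint") -> int:
        """Representative point: interval midpoint or strand-aware 5' end."""
        if kind == "midpoint":
            return self.midpoint
        if kind == "start5":
            return self.start if self.strand != "-" else self.end - 1
        raise ValueError(f"unknown anchor kind {kind!r}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene symbol with one annotated TSS (0-based position)."""

    gene_symbol: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_symbol!r}: strand must be + or -, got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_symbol!r}: negative TSS")


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide variant position (0-based)."""

    snp_id: str
    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"SNP {self.snp_id!r}: negative position")


@dataclass(frozen=True)
class AssociationRecord:
    """One enhancer-promoter association with its expression-correlation score."""

    enhancer_id: str
    promoter_id: str
    score: float

    def __post_init__(self):
        if not self.enhancer_id or not self.promoter_id:
            raise ValidationError("association with empty enhancer or promoter id")
        if not np.isfinite(self.score):
            raise ValidationError(
                f"association {self.enhancer_id!r}-{self.promoter_id!r}: "
                f"non-finite score"
            )


def filter_by_region(
    features: Iterable[GenomicFeature], chrom: str, start: int, end: int
) -> list[str]:
    """Ids of features overlapping [start, end) on chrom by at least 1 bp."""
    if not (0 <= start < end):
        raise ValidationError(f"invalid query region [{start}, {end})")
    return [
        f.feature_id
        for f in features
        if f.chrom == chrom and f.start < end and f.end > start
    ]


def filter_by_gene_window(
    features: Iterable[GenomicFeature],
    genes: Iterable[GeneRecord],
    gene_symbol: str,
    window_bp: int = DEFAULT_GENE_WINDOW,
    anchor: Literal["midpoint", "start5"] = "midpoint",
) -> list[str]:
    """Ids of features whose anchor lies within window_bp of the gene's TSS.

    The window is the closed interval [tss - window_bp, tss + window_bp]
    on the gene's chromosome.  A gene with several annotated TSSs
    contributes the union of the per-TSS windows.  Unknown symbols raise
    :class:`UnknownGeneError` with case-insensitive close matches.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    genes = list(genes)
    matches = [g for g in genes if g.gene_symbol == gene_symbol]
    if not matches:  # tolerate case differences before giving up
        matches = [g for g in genes if g.gene_symbol.lower() == gene_symbol.lower()]
    if not matches:
        symbols = sorted({g.gene_symbol for g in genes})
        suggestions = difflib.get_close_matches(
            gene_symbol.lower(), [s.lower() for s in symbols], n=3
        )
        by_lower = {s.lower(): s for s in symbols}
        raise UnknownGeneError(gene_symbol, [by_lower[s] for s in suggestions])
    out = []
    for f in features:
        point = f.anchor(anchor)
        for g in matches:
            if f.chrom == g.chrom and g.tss - window_bp <= point <= g.tss + window_bp:
                out.append(f.feature_id)
                break
    return out


def snp_overlap(
    enhancers: Iterable[GenomicFeature],
    snps: Iterable[SNPRecord],
    max_dist: int = DEFAULT_SNP_MAX_DIST,
) -> set[tuple[str, str]]:
    """(enhancer_id, snp_id) pairs with midpoint-to-SNP distance <= max_dist.

    Per-chromosome sorted SNP positions plus two binary searches per
    enhancer keep this near-linear; results are a set, so each
    qualifying pair appears exactly once regardless of input order.
    """
    if max_dist < 0:
        raise ValidationError("max_dist must be >= 0")
    by_chrom: dict[str, list[SNPRecord]] = defaultdict(list)
    for s in snps:
        by_chrom[s.chrom].append(s)
    sorted_pos: dict[str, tuple[np.ndarray, list[SNPRecord]]] = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.pos)
        sorted_pos[chrom] = (np.array([r.pos for r in recs]), recs)
    pairs: set[tuple[str, str]] = set()
    for e in enhancers:
        if e.chrom not in sorted_pos:
            continue
        pos, recs = sorted_pos[e.chrom]
        mid = e.midpoint
        lo = int(np.searchsorted(pos, mid - max_dist, side="left"))
        hi = int(np.searchsorted(pos, mid + max_dist, side="right"))
        for r in recs[lo:hi]:
            pairs.add((e.feature_id, r.snp_id))
    return pairs


def link_associations(
    selected_enhancer_ids: Iterable[str],
    table: Iterable[AssociationRecord],
) -> Mapping[str, list[tuple[str, float]]]:
    """Associated promoter ids and scores per selected enhancer.

    Pure pass-through annotation: scores come from the supplied table,
    no correlation is computed.  Duplicate table rows are deduplicated;
    enhancers absent from the table map to an empty list.
    """
    by_enh: dict[str, list[tuple[str, float]]] = defaultdict(list)
    seen: set[tuple[str, str, float]] = set()
    for rec in table:
        key = (rec.enhancer_id, rec.promoter_id, rec.score)
        if key not in seen:
            seen.add(key)
            by_enh[rec.enhancer_id].append((rec.promoter_id, rec.score))
    return {e: by_enh.get(e, []) for e in selected_enhancer_ids}
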