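"""Variant and transcript-model primitives.

Represents single heterozygous variants (SNV / simple insertion / simple
deletion), computes genomic and cDNA distances between a variant pair, and
maps positions between genomic and transcript (cDNA) coordinate systems
through an exon model.

Coordinate conventions: 1-based closed intervals everywhere (HGVS/VCF
style).  BED12 input is converted at the reader boundary (see
:mod:`ampliphase.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional

_VALID_BASES = frozenset("ACGT")


class VariantKind(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


def _classify(ref: str, alt: str) -> VariantKind:
    if len(ref) == 1 and len(alt) == 1:
        return VariantKind.SNV
    if len(alt) > len(ref) and alt.startswith(ref):
        return VariantKind.INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantKind.DELETION
    raise ValueError(f"complex variant {ref}>{alt} not supported")


@dataclass(frozen=True)
class Variant:
    """One heterozygous variant.

    Parameters
    ----------
    chrom : chromosome / sequence name.
    gpos : 1-based position of the first reference base affected.
    ref, alt : uppercase ACGT allele strings (non-empty, distinct).
    cdna_pos : optional 1-based cDNA (c.) coordinate.
    label : free-text identifier.
    """

    chrom: str
    gpos: int
    ref: str
    alt: str
    cdna_pos: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.gpos < 1:
            raise ValueError(f"gpos must be >= 1, got {self.gpos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} allele {allele!r} is not uppercase ACGT")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.cdna_pos is not None and self.cdna_pos < 1:
            raise ValueError("cdna_pos must be >= 1")
        _classify(self.ref, self.alt)  # reject complex alleles up front

    @property
    def kind(self) -> VariantKind:
        return _classify(self.ref, self.alt)

    @property
    def inserted(self) -> str:
        """Bases added by an insertion (empty otherwise)."""
        return self.alt[len(self.ref):] if self.kind is VariantKind.INSERTION else ""

    @property
    def deleted(self) -> str:
        """Bases removed by a deletion (empty otherwise)."""
        return self.ref[len(self.alt):] if self.kind is VariantKind.DELETION else ""

    def __str__(self) -> str:
        return f"{self.chrom}:{self.gpos}:{self.ref}:{self.alt}"


def genomic_distance_kb(v1: Variant, v2: Variant) -> tuple[int, float]:
    """Distance between two variants on the genome.

    Returns ``(bp, kb)`` where *bp* is the absolute coordinate difference
    and *kb* is bp/1000 rounded half-up to one decimal.
    """
    if v1.chrom != v2.chrom:
        raise ValueError("cross-chromosome phase not supported")
    bp = abs(v2.gpos - v1.gpos)
    kb = float((Decimal(bp) / Decimal(1000)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return bp, kb


def cdna_span_bp(c1: int, c2: int) -> int:
    """Inclusive base span between two cDNA coordinates: ``|c2 - c1| + 1``."""
    if c1 < 1 or c2 < 1:
        raise ValueError("cDNA coordinates must be >= 1")
    return abs(c2 - c1) + 1


@dataclass(frozen=True)
class TranscriptModel:
    """Exon model of a transcript for genomic<->cDNA coordinate mapping.

    ``exons`` are 1-based closed genomic intervals listed in transcript
    5'->3' order: starts strictly increase on '+', strictly decrease on '-'.
    ``cds_start_tpos`` is the 1-based transcript coordinate of the first
    coding base.
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_tpos: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("transcript has no exons")
        for s, e in exons:
            if s < 1 or e < s:
                raise ValueError(f"bad exon interval [{s},{e}]")
        starts = [s for s, _ in exons]
        ordered = all(a < b for a, b in zip(starts, starts[1:])) if self.strand == "+" \
            else all(a > b for a, b in zip(starts, starts[1:]))
        if not ordered:
            raise ValueError("exon starts must be strictly monotonic in transcript order")
        spans = sorted(exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        if not 1 <= self.cds_start_tpos <= self.length:
            raise ValueError("cds_start_tpos outside transcript")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def map_genomic_to_transcript(self, gpos: int) -> int:
        """1-based transcript coordinate of an exonic genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                within = (gpos - s + 1) if self.strand == "+" else (e - gpos + 1)
                return offset + within
            offset += e - s + 1
        raise ValueError(f"position not exonic: {self.chrom}:{gpos}")

    def map_transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`map_genomic_to_transcript`."""
        if tpos < 1 or tpos > self.length:
            raise ValueError(f"transcript position out of range: {tpos}")
        remaining = tpos
        for s, e in self.exons:
            n = e - s + 1
            if remaining <= n:
                return (s + remaining - 1) if self.strand == "+" else (e - remaining + 1)
            remaining -= n
        raise AssertionError("unreachable")

    def map_transcript_to_cds(self, tpos: int) -> int:
        """Transcript coordinate relative to the CDS start (c. numbering)."""
        return tpos - self.cds_start_tpos + 1
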