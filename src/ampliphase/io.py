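"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, FASTQ via the fast ``FastqGeneralIterator`` (gzip
transparent), SAM/BAM via pysam (used purely as a read-pair container —
no CIGAR is ever consulted for allele calling), minimal VCF via pysam,
transcript models from BED12 or a simple TSV, and TSV/JSON reports.
"""

from __future__ import annotations

import gzip
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Iterator, Optional

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .variants import TranscriptModel, Variant


@dataclass(frozen=True)
class RawPair:
    """A paired-end read before UMI extraction."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    anchor: Optional[Hashable] = None


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: uppercase sequence}`` mapping.

    Names are the first whitespace token.  Empty files and duplicate names
    are errors.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate FASTA record name {record.id!r}")
            sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def _strip_mate_suffix(name: str) -> str:
    head = name.split()[0].split("\t")[0]
    if head.endswith("/1") or head.endswith("/2"):
        head = head[:-2]
    return head


def read_fastq_pairs(path_r1, path_r2) -> Iterator[RawPair]:
    """Stream name-synchronized pairs from two 4-line FASTQ files."""
    with _open_text(path_r1) as h1, _open_text(path_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        lineno = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError(f"truncated FASTQ pair near record {lineno // 4 + 1} "
                                 f"(line {lineno + 1}): files have unequal record counts")
            name1 = _strip_mate_suffix(rec1[0])
            name2 = _strip_mate_suffix(rec2[0])
            if name1 != name2:
                raise ValueError(f"desynchronized read names at line {lineno + 1}: "
                                 f"{name1!r} != {name2!r}")
            yield RawPair(name=name1, seq1=rec1[1].upper(), qual1=rec1[2],
                          seq2=rec2[1].upper(), qual2=rec2[2])
            lineno += 4


def write_fastq_pairs(pairs: Iterable[RawPair], path_r1, path_r2) -> None:
    with _open_text(path_r1, "wt") as o1, _open_text(path_r2, "wt") as o2:
        for p in pairs:
            o1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            o2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_alignment_pairs(path) -> Iterator[RawPair]:
    """Stream read pairs from SAM/BAM, paired up by query name.

    Only primary alignments are used; sequences are returned as stored
    (reference-forward for mapped reads).  Unmapped mates are retained.
    The anchor is the smaller of the two alignment starts (or None when
    both mates are unmapped), for positional duplicate grouping.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            first, second = (mate, aln) if mate.is_read1 else (aln, mate)
            starts = [a.reference_start for a in (first, second)
                      if not a.is_unmapped and a.reference_start is not None]
            anchor = min(starts) if starts else None
            yield RawPair(
                name=first.query_name,
                seq1=(first.query_sequence or "").upper(),
                qual1=pysam.qualities_to_qualitystring(first.query_qualities or []),
                seq2=(second.query_sequence or "").upper(),
                qual2=pysam.qualities_to_qualitystring(second.query_qualities or []),
                anchor=anchor,
            )
    if pending:
        names = ", ".join(sorted(pending)[:3])
        raise ValueError(f"unpaired primary alignments remain (e.g. {names})")


def parse_variant_literal(text: str, cdna_pos: Optional[int] = None,
                          label: str = "") -> Variant:
    """Parse ``CHROM:POS:REF:ALT`` (e.g. ``chr13:51958362:G:GG``)."""
    parts = text.strip().split(":")
    if len(parts) != 4:
        raise ValueError(f"variant literal {text!r} is not CHROM:POS:REF:ALT")
    chrom, pos, ref, alt = parts
    return Variant(chrom=chrom, gpos=int(pos), ref=ref.upper(), alt=alt.upper(),
                   cdna_pos=cdna_pos, label=label or text.strip())


def read_vcf_variants(path) -> list[Variant]:
    """Read a minimal VCF: CHROM, POS, REF, first ALT.  No normalization."""
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            variants.append(Variant(chrom=rec.chrom, gpos=rec.pos,
                                    ref=rec.ref.upper(), alt=rec.alts[0].upper(),
                                    label=rec.id or ""))
    return variants


def read_transcript_bed12(path, cds_start_tpos: int = 1) -> TranscriptModel:
    """Read a single-record BED12 into a TranscriptModel.

    BED is 0-based half-open; intervals are converted to 1-based closed.
    Blocks are stored in transcript 5'->3' order (reversed for '-').
    """
    with _open_text(path) as handle:
        lines = [ln for ln in handle if ln.strip() and not ln.startswith(("#", "track"))]
    if len(lines) != 1:
        raise ValueError(f"expected exactly one BED12 record, got {len(lines)}")
    f = lines[0].rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError("BED12 record has fewer than 12 columns")
    chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = [(chrom_start + st + 1, chrom_start + st + sz)
             for st, sz in zip(starts, sizes)]
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(name=name, chrom=chrom, strand=strand,
                           exons=tuple(exons), cds_start_tpos=cds_start_tpos)


def read_transcript_tsv(path, cds_start_tpos: int = 1) -> TranscriptModel:
    """Read a 4-column TSV: name, chrom, strand, comma-separated exon
    intervals like ``1001-1050,2001-2100`` (1-based closed, transcript
    order)."""
    with _open_text(path) as handle:
        lines = [ln for ln in handle if ln.strip() and not ln.startswith("#")]
    if len(lines) != 1:
        raise ValueError(f"expected exactly one transcript record, got {len(lines)}")
    name, chrom, strand, exon_text = lines[0].rstrip("\n").split("\t")[:4]
    exons = []
    for token in exon_text.split(","):
        s, e = token.split("-")
        exons.append((int(s), int(e)))
    return TranscriptModel(name=name, chrom=chrom, strand=strand,
                           exons=tuple(exons), cds_start_tpos=cds_start_tpos)


def write_report(results: dict, out_dir, basename: str = "report",
                 formats: tuple[str, ...] = ("json", "tsv")) -> list[Path]:
    """Write the pipeline report as JSON and/or TSV with stable field order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = out_dir / f"{basename}.json"
        with open(path, "w") as out:
            json.dump(results, out, indent=2, sort_keys=False)
            out.write("\n")
        written.append(path)
    if "tsv" in formats:
        path = out_dir / f"{basename}.tsv"
        with open(path, "w") as out:
            out.write("section\tfield\tvalue\n")
            for section, payload in results.items():
                if isinstance(payload, dict):
                    for key, value in payload.items():
                        out.write(f"{section}\t{key}\t{_scalar(value)}\n")
                else:
                    out.write(f"{section}\t-\t{_scalar(payload)}\n")
        written.append(path)
    return written


def _scalar(value) -> str:
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (dict, list, tuple)):
        return json.dumps(value)
    return str(value)
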