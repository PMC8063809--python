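"""Allele-distinguishing sequence contexts and exact-match allele calling.

A variant is typed in a read by searching for short k-mers ("contexts")
built around the edited bases: one k-mer for the reference allele and one
for the alternate allele.  Matching is exact; for insertions inside a
homopolymer run the contexts are extended past the run on both sides so
that neither k-mer is a substring of the other (a 6-G run plus anchors is
distinguishable from a 7-G run plus the same anchors, whereas the bare
runs are not).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .variants import Variant

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class AlleleCall(str, Enum):
    REF = "REF"
    ALT = "ALT"
    NONE = "NONE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ContextPair:
    """Ref/alt context k-mers for one variant, reference-forward."""

    variant: Variant
    ref_context: str
    alt_context: str
    flank_left: int
    flank_right: int
    orientation: str = "reference_forward"

    @property
    def distinguishable(self) -> bool:
        return (self.ref_context not in self.alt_context
                and self.alt_context not in self.ref_context)


def _distinguishable(ref_ctx: str, alt_ctx: str) -> bool:
    return ref_ctx not in alt_ctx and alt_ctx not in ref_ctx


def build_contexts(ref_window: str, variant_offset: int, variant: Variant,
                   flank: int = 4) -> ContextPair:
    """Build the ref/alt context pair for ``variant`` inside ``ref_window``.

    ``variant_offset`` is the 0-based offset of ``variant.ref`` within the
    window.  The context is the window slice spanning ``flank`` bases on
    each side of the edited region.  Flanks are auto-extended: when the
    window truncates one flank, the full remaining window on the opposite
    side is used; and the region keeps growing symmetrically until neither
    context is a substring of the other (which, for an indel touching a
    homopolymer run, forces the whole run plus at least one non-run anchor
    base on each side into both contexts).

    Raises ``ValueError`` if the window disagrees with the variant or is
    exhausted before the contexts become distinguishable.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    window = ref_window.upper()
    ref, alt = variant.ref, variant.alt
    if window[variant_offset:variant_offset + len(ref)] != ref:
        raise ValueError("reference window disagrees with variant "
                         f"(expected {ref!r} at offset {variant_offset})")

    n = len(window)
    start = variant_offset - flank
    end = variant_offset + len(ref) + flank
    clipped_left, clipped_right = start < 0, end > n
    start, end = max(start, 0), min(end, n)
    # A flank truncated by the window edge is compensated by taking the
    # whole remaining window on the other side.
    if clipped_left:
        end = n
    if clipped_right:
        start = 0

    while True:
        ref_ctx = window[start:end]
        alt_ctx = window[start:variant_offset] + alt + window[variant_offset + len(ref):end]
        if _distinguishable(ref_ctx, alt_ctx):
            break
        if start == 0 and end == n:
            raise ValueError("window exhausted before ref/alt contexts "
                             "became distinguishable")
        if start > 0:
            start -= 1
        if end < n:
            end += 1

    return ContextPair(variant=variant, ref_context=ref_ctx, alt_context=alt_ctx,
                       flank_left=variant_offset - start,
                       flank_right=end - (variant_offset + len(ref)))


def match_allele(read_seq: str, cp: ContextPair, both_strands: bool = False) -> AlleleCall:
    """Call the allele carried by ``read_seq`` by exact substring search.

    Returns ALT if only the alt context occurs, REF if only the ref
    context occurs, NONE if neither, AMBIGUOUS if both.  With
    ``both_strands`` the reverse complements are searched too (raw FASTQ
    input, where read orientation is unknown).
    """
    seq = read_seq.upper()
    has_ref = cp.ref_context in seq
    has_alt = cp.alt_context in seq
    if both_strands:
        has_ref = has_ref or revcomp(cp.ref_context) in seq
        has_alt = has_alt or revcomp(cp.alt_context) in seq
    if has_ref and has_alt:
        return AlleleCall.AMBIGUOUS
    if has_alt:
        return AlleleCall.ALT
    if has_ref:
        return AlleleCall.REF
    return AlleleCall.NONE
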