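"""UMI extraction and PCR-duplicate collapsing.

Duplicates are collapsed before any allele counting.  Two grouping methods
are provided: ``exact`` (identical UMI + anchor) and ``directional``
(adjacency clustering: a directed edge a->b exists when Hamming(a,b) <= 1
and count(a) >= 2*count(b) - 1; each greedy reachability component from
its highest-count node collapses to one representative).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Hashable, Iterable, Optional, Sequence

from .io import RawPair

_VALID_UMI = frozenset("ACGT")


@dataclass(frozen=True)
class TaggedPair:
    """A read pair with its UMI extracted."""

    name: str
    umi: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    anchor: Optional[Hashable] = None

    def __post_init__(self) -> None:
        if not self.umi or not set(self.umi) <= _VALID_UMI:
            raise ValueError(f"UMI {self.umi!r} is not uppercase ACGT ({self.name})")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.name}")

    @property
    def mean_quality(self) -> float:
        quals = self.qual1 + self.qual2
        if not quals:
            return 0.0
        return sum(ord(c) - 33 for c in quals) / len(quals)


@dataclass(frozen=True)
class DedupStats:
    input_pairs: int
    kept_pairs: int
    method: str

    @property
    def duplicates_removed(self) -> int:
        return self.input_pairs - self.kept_pairs


def extract_umi(pair: RawPair, scheme: str = "name_suffix", umi_len: int = 8) -> TaggedPair:
    """Pull the UMI out of a raw pair.

    ``name_suffix``: read name ends with ``_<UMI>`` (UMI-tools style).
    ``inline_prefix``: mate 1 starts with ``umi_len`` UMI bases, which are
    trimmed from seq1/qual1.
    """
    if scheme == "name_suffix":
        name, sep, umi = pair.name.rpartition("_")
        if not sep or len(umi) != umi_len or not set(umi) <= _VALID_UMI:
            raise ValueError(f"read name {pair.name!r} has no _UMI suffix of length {umi_len}")
        return TaggedPair(name=pair.name, umi=umi, seq1=pair.seq1, seq2=pair.seq2,
                          qual1=pair.qual1, qual2=pair.qual2, anchor=pair.anchor)
    if scheme == "inline_prefix":
        if len(pair.seq1) <= umi_len:
            raise ValueError(f"read {pair.name!r} shorter than UMI length {umi_len}")
        umi = pair.seq1[:umi_len]
        return TaggedPair(name=pair.name, umi=umi,
                          seq1=pair.seq1[umi_len:], seq2=pair.seq2,
                          qual1=pair.qual1[umi_len:], qual2=pair.qual2,
                          anchor=pair.anchor)
    raise ValueError(f"unknown UMI scheme {scheme!r}")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def cluster_directional(counts: dict[str, int]) -> dict[str, str]:
    """Map each UMI to its cluster representative (directional rule).

    Nodes are visited in descending count (ties broken lexicographically);
    each unassigned node seeds a cluster and absorbs every unassigned UMI
    reachable along directed edges a->b with Hamming(a, b) <= 1 and
    count(a) >= 2*count(b) - 1.
    """
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    adjacency: dict[str, list[str]] = {u: [] for u in umis}
    for i, a in enumerate(umis):
        for b in umis[i + 1:]:
            if _hamming(a, b) <= 1:
                if counts[a] >= 2 * counts[b] - 1:
                    adjacency[a].append(b)
                if counts[b] >= 2 * counts[a] - 1:
                    adjacency[b].append(a)
    assignment: dict[str, str] = {}
    for seed in umis:
        if seed in assignment:
            continue
        stack = [seed]
        assignment[seed] = seed
        while stack:
            node = stack.pop()
            for nbr in adjacency[node]:
                if nbr not in assignment:
                    assignment[nbr] = seed
                    stack.append(nbr)
    return assignment


def dedup(pairs: Sequence[TaggedPair], method: str = "directional") -> tuple[list[TaggedPair], DedupStats]:
    """Collapse PCR duplicates, keeping one representative per molecule.

    Grouping key is (UMI cluster, anchor).  The representative is the pair
    with the highest mean base quality, ties broken by lexicographically
    smallest name.  Output preserves input order of the representatives.
    """
    if method not in ("exact", "directional"):
        raise ValueError(f"unknown dedup method {method!r}")
    pairs = list(pairs)
    if not pairs:
        return [], DedupStats(0, 0, method)
    umi_lens = {len(p.umi) for p in pairs}
    if len(umi_lens) > 1:
        raise ValueError(f"mixed UMI lengths: {sorted(umi_lens)}")

    by_anchor: dict[Hashable, list[TaggedPair]] = defaultdict(list)
    for p in pairs:
        by_anchor[p.anchor].append(p)

    kept: list[TaggedPair] = []
    for group in by_anchor.values():
        if method == "exact":
            assignment = {u: u for u in {p.umi for p in group}}
        else:
            counts = Counter(p.umi for p in group)
            assignment = cluster_directional(dict(counts))
        clusters: dict[str, list[TaggedPair]] = defaultdict(list)
        for p in group:
            clusters[assignment[p.umi]].append(p)
        for members in clusters.values():
            kept.append(min(members, key=lambda p: (-p.mean_quality, p.name)))

    order = {id(p): i for i, p in enumerate(pairs)}
    kept.sort(key=lambda p: order[id(p)])
    return kept, DedupStats(len(pairs), len(kept), method)
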