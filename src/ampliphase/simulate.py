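"""Paired-end amplicon read simulator with per-pair ground truth.

Generates reads from a two-variant amplicon with known phase
(CIS/TRANS), haplotype expression ratio, substitution errors, per-molecule
UMIs, and PCR duplication.  Two library modes are supported:

* ``amplicon`` — direct adapter ligation: every fragment is the full
  molecule, so the two mates read in from the amplicon ends and can
  jointly span both variant sites.
* ``fragmentation`` — tagmentation-style: fragment length is drawn from a
  truncated normal, so most pairs cover at most one site.

Everything is deterministic given the seed; the truth table records, for
every emitted pair, its source haplotype, UMI, fragment interval, the
allele readable at each site, and which original molecule it duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .contexts import ContextPair, build_contexts, revcomp
from .io import RawPair
from .variants import Variant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_AMPLICON_LEN = 621
DEFAULT_READ_LEN = 250
DEFAULT_SITE_A_POS = 79    # SNV
DEFAULT_SITE_B_POS = 542   # single-base duplication; inclusive span = 464

_QUAL_CHAR = chr(37 + 33)  # constant Phred 37


@dataclass(frozen=True)
class SimConfig:
    configuration: str = "TRANS"
    n_pairs: int = 1000
    hap1_fraction: float = 0.5
    ref_amplicon: Optional[str] = None
    variant_a: Optional[Variant] = None
    variant_b: Optional[Variant] = None
    read_len: int = DEFAULT_READ_LEN
    library_mode: str = "amplicon"
    fragment_len_mean: float = 350.0
    fragment_len_sd: float = 60.0
    sub_error_rate: float = 0.0
    umi_len: int = 8
    pcr_duplication_mean: float = 1.0
    pcr_bias_hap1: float = 1.0
    flank: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.configuration not in ("CIS", "TRANS"):
            raise ValueError(f"configuration must be CIS or TRANS, got {self.configuration!r}")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not 0.0 < self.hap1_fraction < 1.0:
            raise ValueError("hap1_fraction must lie in (0, 1)")
        if self.library_mode not in ("amplicon", "fragmentation"):
            raise ValueError(f"unknown library_mode {self.library_mode!r}")
        if not 0.0 <= self.sub_error_rate <= 0.2:
            raise ValueError("sub_error_rate must lie in [0, 0.2]")
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")
        if self.pcr_duplication_mean < 1.0:
            raise ValueError("pcr_duplication_mean must be >= 1")
        if self.pcr_bias_hap1 <= 0.0:
            raise ValueError("pcr_bias_hap1 must be > 0")
        if self.fragment_len_mean <= 0 or self.fragment_len_sd < 0:
            raise ValueError("bad fragment length parameters")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    name: str           # emitted pair name (includes the _UMI suffix)
    haplotype: int      # 1 or 2
    umi: str
    frag_start: int     # 0-based half-open interval on the haplotype
    frag_end: int
    allele_a: Optional[str]   # REF/ALT when the pair spans site A, else None
    allele_b: Optional[str]
    duplicate_of: str   # name of the original molecule's pair (self if original)

TRUTH_COLUMNS = ("name", "haplotype", "umi", "frag_start", "frag_end",
                 "allele_a", "allele_b", "duplicate_of")


def random_amplicon(rng: np.random.Generator, length: int = DEFAULT_AMPLICON_LEN) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _next_base(base: str) -> str:
    order = "ACGT"
    return order[(order.index(base) + 1) % 4]


def default_variants(ref_amplicon: str, chrom: str = "amplicon") -> tuple[Variant, Variant]:
    """Default two-variant layout: an SNV and a single-base duplication
    whose inclusive cDNA span is 464 bp, inside a 621-bp amplicon."""
    a_base = ref_amplicon[DEFAULT_SITE_A_POS - 1]
    b_base = ref_amplicon[DEFAULT_SITE_B_POS - 1]
    variant_a = Variant(chrom=chrom, gpos=DEFAULT_SITE_A_POS, ref=a_base,
                        alt=_next_base(a_base), label="siteA")
    variant_b = Variant(chrom=chrom, gpos=DEFAULT_SITE_B_POS, ref=b_base,
                        alt=b_base + b_base, label="siteB")
    return variant_a, variant_b


def resolve_config(cfg: SimConfig) -> SimConfig:
    """Fill in the generated amplicon and default variants (deterministic
    per seed) and validate the resolved geometry."""
    ref = cfg.ref_amplicon
    if ref is None:
        ref = random_amplicon(np.random.default_rng([cfg.seed, 0xA3]))
    va, vb = cfg.variant_a, cfg.variant_b
    if va is None or vb is None:
        da, db = default_variants(ref)
        va = va or da
        vb = vb or db
    resolved = replace(cfg, ref_amplicon=ref, variant_a=va, variant_b=vb)
    _validate_geometry(resolved)
    return resolved


def _validate_geometry(cfg: SimConfig) -> None:
    ref, va, vb = cfg.ref_amplicon, cfg.variant_a, cfg.variant_b
    if cfg.read_len > len(ref):
        raise ValueError("read_len exceeds amplicon length")
    for v in (va, vb):
        s = v.gpos - 1
        if not 0 <= s <= len(ref) - len(v.ref):
            raise ValueError(f"variant {v} outside amplicon")
        if ref[s:s + len(v.ref)] != v.ref:
            raise ValueError(f"amplicon disagrees with variant {v}")
    a_span = range(va.gpos, va.gpos + len(va.ref))
    b_span = range(vb.gpos, vb.gpos + len(vb.ref))
    if set(a_span) & set(b_span):
        raise ValueError("variants overlap")


def _apply_edit(seq: str, variant: Variant) -> str:
    s = variant.gpos - 1
    return seq[:s] + variant.alt + seq[s + len(variant.ref):]


def build_haplotypes(ref_amplicon: str, variant_a: Variant, variant_b: Variant,
                     configuration: str) -> tuple[str, str]:
    """Construct the two haplotype sequences.

    TRANS: hap1 = alt_A + ref_B, hap2 = ref_A + alt_B.
    CIS:   hap1 = alt_A + alt_B, hap2 = ref_A + ref_B.
    Edits are applied from the downstream variant first so earlier
    coordinates stay valid under indel shifts.
    """
    if configuration not in ("CIS", "TRANS"):
        raise ValueError(f"configuration must be CIS or TRANS, got {configuration!r}")
    a_span = range(variant_a.gpos, variant_a.gpos + len(variant_a.ref))
    b_span = range(variant_b.gpos, variant_b.gpos + len(variant_b.ref))
    if set(a_span) & set(b_span):
        raise ValueError("variants overlap")

    def make(with_a: bool, with_b: bool) -> str:
        seq = ref_amplicon
        for v, use in sorted(((variant_a, with_a), (variant_b, with_b)),
                             key=lambda t: -t[0].gpos):
            if use:
                seq = _apply_edit(seq, v)
        return seq

    if configuration == "TRANS":
        return make(True, False), make(False, True)
    return make(True, True), make(False, False)


def _hap_alleles(configuration: str) -> dict[int, tuple[str, str]]:
    if configuration == "TRANS":
        return {1: ("ALT", "REF"), 2: ("REF", "ALT")}
    return {1: ("ALT", "ALT"), 2: ("REF", "REF")}


def _context_interval(variant: Variant, cp: ContextPair, allele: str,
                      shift: int) -> tuple[int, int]:
    """0-based half-open interval of the allele's context on a haplotype
    whose coordinates are offset by ``shift`` upstream-indel bases."""
    core_start = variant.gpos - 1 + shift
    core_len = len(variant.ref) if allele == "REF" else len(variant.alt)
    return core_start - cp.flank_left, core_start + core_len + cp.flank_right


_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # substitute with one of the three other bases, uniformly
        offsets = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        arr[hit] = _BASES[(_BASE_INDEX[arr[hit]] + offsets) % 4]
    return bytes(arr).decode()


def simulate_pairs(cfg: SimConfig) -> tuple[list[RawPair], list[TruthRecord]]:
    """Generate read pairs and the matching truth table.

    Per molecule: haplotype ~ Bernoulli(hap1_fraction); fragment = whole
    molecule (amplicon mode) or truncated-normal slice (fragmentation
    mode); one UMI drawn uniformly; PCR copy number
    k ~ 1 + Poisson(lambda) with lambda = (pcr_duplication_mean - 1),
    scaled by ``pcr_bias_hap1`` for haplotype 1; substitution errors
    i.i.d. per emitted base.  Read names carry the UMI as a ``_UMI``
    suffix.  Deterministic given ``cfg.seed``.
    """
    cfg = resolve_config(cfg)
    rng = np.random.default_rng([cfg.seed, 0xF1])
    ref, va, vb = cfg.ref_amplicon, cfg.variant_a, cfg.variant_b
    hap1, hap2 = build_haplotypes(ref, va, vb, cfg.configuration)
    hapseqs = {1: hap1, 2: hap2}
    alleles = _hap_alleles(cfg.configuration)

    cp_a = build_contexts(ref, va.gpos - 1, va, flank=cfg.flank)
    cp_b = build_contexts(ref, vb.gpos - 1, vb, flank=cfg.flank)

    # context intervals per haplotype, in haplotype coordinates
    intervals: dict[int, tuple[tuple[int, int], tuple[int, int]]] = {}
    for hap in (1, 2):
        allele_a, allele_b = alleles[hap]
        # indel shift affects only coordinates downstream of the edit
        shift_b = (len(va.alt) - len(va.ref)) if allele_a == "ALT" and va.gpos < vb.gpos else 0
        shift_a = (len(vb.alt) - len(vb.ref)) if allele_b == "ALT" and vb.gpos < va.gpos else 0
        intervals[hap] = (
            _context_interval(va, cp_a, allele_a, shift_a),
            _context_interval(vb, cp_b, allele_b, shift_b),
        )

    pairs: list[RawPair] = []
    truth: list[TruthRecord] = []
    lam_base = cfg.pcr_duplication_mean - 1.0
    name_width = max(6, len(str(max(cfg.n_pairs - 1, 0))))

    for i in range(cfg.n_pairs):
        hap = 1 if rng.random() < cfg.hap1_fraction else 2
        seq = hapseqs[hap]
        if cfg.library_mode == "amplicon":
            fs, fe = 0, len(seq)
        else:
            flen = int(round(rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd)))
            flen = max(30, min(flen, len(seq)))
            fs = int(rng.integers(0, len(seq) - flen + 1))
            fe = fs + flen
        frag = seq[fs:fe]
        m1 = (fs, fs + min(cfg.read_len, len(frag)))
        m2 = (fe - min(cfg.read_len, len(frag)), fe)

        def spanned(interval: tuple[int, int]) -> bool:
            lo, hi = interval
            return (m1[0] <= lo and hi <= m1[1]) or (m2[0] <= lo and hi <= m2[1])

        allele_a = alleles[hap][0] if spanned(intervals[hap][0]) else None
        allele_b = alleles[hap][1] if spanned(intervals[hap][1]) else None

        umi = bytes(_BASES[rng.integers(0, 4, size=cfg.umi_len)]).decode()
        lam = lam_base * (cfg.pcr_bias_hap1 if hap == 1 else 1.0)
        k = 1 + int(rng.poisson(lam)) if lam > 0 else 1

        base = f"sim{i:0{name_width}d}"
        original = f"{base}_{umi}"
        mate1_clean = frag[:cfg.read_len]
        mate2_clean = revcomp(frag)[:cfg.read_len]
        for j in range(k):
            name = original if j == 0 else f"{base}.d{j}_{umi}"
            seq1 = _add_errors(mate1_clean, cfg.sub_error_rate, rng)
            seq2 = _add_errors(mate2_clean, cfg.sub_error_rate, rng)
            pairs.append(RawPair(name=name, seq1=seq1, qual1=_QUAL_CHAR * len(seq1),
                                 seq2=seq2, qual2=_QUAL_CHAR * len(seq2)))
            truth.append(TruthRecord(name=name, haplotype=hap, umi=umi,
                                     frag_start=fs, frag_end=fe,
                                     allele_a=allele_a, allele_b=allele_b,
                                     duplicate_of=original))
    return pairs, truth


def write_truth_tsv(records: list[TruthRecord], path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in records:
            out.write("\t".join(
                "" if getattr(r, c) is None else str(getattr(r, c))
                for c in TRUTH_COLUMNS) + "\n")


def read_truth_tsv(path) -> list[TruthRecord]:
    records: list[TruthRecord] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth table header in {path}")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            records.append(TruthRecord(
                name=f[0], haplotype=int(f[1]), umi=f[2],
                frag_start=int(f[3]), frag_end=int(f[4]),
                allele_a=f[5] or None, allele_b=f[6] or None,
                duplicate_of=f[7]))
    return records
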