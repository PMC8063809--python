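"""End-to-end pipeline: reads -> allele calls -> dedup -> phase + ASE report."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

from . import __version__
from .contexts import AlleleCall, build_contexts, match_allele
from .expression import (SiteAlleleCounts, haplotype_expression, imbalance_test)
from .io import RawPair, parse_variant_literal, read_alignment_pairs, read_fasta, read_fastq_pairs
from .phasing import (Configuration, PairObservation, call_phase, merge_mate_calls,
                      summarize_run, tabulate)
from .umi import TaggedPair, dedup, extract_umi
from .variants import Variant

log = logging.getLogger("ampliphase")


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run (echoed into reports)."""

    reference: str = ""                 # FASTA path
    r1: Optional[str] = None
    r2: Optional[str] = None
    alignment: Optional[str] = None     # SAM/BAM path (alternative to r1/r2)
    variant_a: str = ""                 # CHROM:POS:REF:ALT literals
    variant_b: str = ""
    flank: int = 4
    both_strands: Optional[bool] = None  # default: True for FASTQ, False for SAM/BAM
    umi_scheme: Optional[str] = "name_suffix"
    umi_len: int = 8
    dedup_method: str = "directional"
    no_dedup: bool = False
    min_informative: int = 10
    min_support_fraction: float = 0.9
    null_fraction: float = 0.5
    alpha: float = 0.05
    log_level: str = "INFO"

    @property
    def input_mode(self) -> str:
        return "bam" if self.alignment else "fastq_pair"

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    report: dict
    phase_configuration: Configuration


def _call_pair(pair: RawPair, cp_a, cp_b, both_strands: bool) -> tuple[AlleleCall, AlleleCall]:
    call_a = merge_mate_calls(match_allele(pair.seq1, cp_a, both_strands),
                              match_allele(pair.seq2, cp_a, both_strands))
    call_b = merge_mate_calls(match_allele(pair.seq1, cp_b, both_strands),
                              match_allele(pair.seq2, cp_b, both_strands))
    return call_a, call_b


def run_phase(config: RunConfig) -> RunResult:
    """Execute the full pipeline described by ``config``."""
    references = read_fasta(config.reference)
    variant_a = parse_variant_literal(config.variant_a, label="siteA")
    variant_b = parse_variant_literal(config.variant_b, label="siteB")

    contexts = []
    for v in (variant_a, variant_b):
        if v.chrom not in references:
            raise ValueError(f"variant sequence {v.chrom!r} not in reference FASTA")
        contexts.append(build_contexts(references[v.chrom], v.gpos - 1, v,
                                       flank=config.flank))
    cp_a, cp_b = contexts

    if config.alignment:
        pair_stream: Iterable[RawPair] = read_alignment_pairs(config.alignment)
        both_strands = config.both_strands if config.both_strands is not None else False
    else:
        if not (config.r1 and config.r2):
            raise ValueError("either --alignment or both --r1/--r2 are required")
        pair_stream = read_fastq_pairs(config.r1, config.r2)
        both_strands = config.both_strands if config.both_strands is not None else True

    use_umi = config.umi_scheme is not None and not config.no_dedup

    raw_count = 0
    calls: dict[str, tuple[AlleleCall, AlleleCall]] = {}
    tagged: list[TaggedPair] = []
    observations: list[PairObservation] = []
    for pair in pair_stream:
        raw_count += 1
        call_a, call_b = _call_pair(pair, cp_a, cp_b, both_strands)
        if use_umi:
            tp = extract_umi(pair, scheme=config.umi_scheme, umi_len=config.umi_len)
            if tp.anchor is None:
                # alignment-free mode: anchor on the pair's allele signature
                tp = TaggedPair(name=tp.name, umi=tp.umi, seq1=tp.seq1, seq2=tp.seq2,
                                qual1=tp.qual1, qual2=tp.qual2,
                                anchor=(call_a.value, call_b.value))
            tagged.append(tp)
            calls[tp.name] = (call_a, call_b)
        else:
            observations.append(PairObservation(pair.name, call_a, call_b))

    duplicates_removed = 0
    if use_umi:
        kept, stats = dedup(tagged, method=config.dedup_method)
        duplicates_removed = stats.duplicates_removed
        observations = [PairObservation(p.name, *calls[p.name]) for p in kept]
        log.info("dedup (%s): %d -> %d pairs", config.dedup_method,
                 stats.input_pairs, stats.kept_pairs)

    table = tabulate(observations)
    phase = call_phase(table, min_informative=config.min_informative,
                       min_support_fraction=config.min_support_fraction)

    site_counts = {}
    imbalance = {}
    for label, variant, picker in (
            ("site_a", variant_a, lambda o: o.call_a),
            ("site_b", variant_b, lambda o: o.call_b)):
        n_ref = sum(1 for o in observations if picker(o) is AlleleCall.REF)
        n_alt = sum(1 for o in observations if picker(o) is AlleleCall.ALT)
        site_counts[label] = {"n_ref": n_ref, "n_alt": n_alt}
        if n_ref + n_alt >= 1:
            result = imbalance_test(SiteAlleleCounts(str(variant), n_ref, n_alt),
                                    null_fraction=config.null_fraction,
                                    alpha=config.alpha)
            imbalance[label] = result.as_dict()

    report = {
        "tool": {"name": "ampliphase", "version": __version__},
        "config": config.as_dict(),
        "contexts": {
            "site_a": {"ref_context": cp_a.ref_context, "alt_context": cp_a.alt_context},
            "site_b": {"ref_context": cp_b.ref_context, "alt_context": cp_b.alt_context},
        },
        "summary": summarize_run(raw_count, table, site_counts,
                                 duplicates_removed=duplicates_removed, phase=phase),
        "allelic_expression": imbalance,
    }
    if phase.configuration in (Configuration.CIS, Configuration.TRANS):
        try:
            report["haplotype_expression"] = haplotype_expression(table, phase).as_dict()
        except ValueError:
            pass
    return RunResult(report=report, phase_configuration=phase.configuration)
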