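"""Per-pair haplotype observations, the 2x2 configuration table, and the
cis/trans call.

Each read pair yields one allele call per variant site (mate evidence
merged).  Pairs informative at both sites populate a 2x2 table of
(site A, site B) in {REF, ALT}^2; cis support is the diagonal
(REF,REF)+(ALT,ALT), trans support the off-diagonal.  The call is the
majority configuration when its support fraction clears a threshold, with
an exact binomial p-value against a symmetric 0.5 null reported for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from scipy.stats import binomtest

from .contexts import AlleleCall


class Configuration(str, Enum):
    CIS = "CIS"
    TRANS = "TRANS"
    AMBIGUOUS = "AMBIGUOUS"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass(frozen=True)
class PairObservation:
    name: str
    call_a: AlleleCall
    call_b: AlleleCall


def merge_mate_calls(c1: AlleleCall, c2: AlleleCall) -> AlleleCall:
    """Merge the two mates' calls at one site.

    NONE defers to the other mate; agreement passes through; REF vs ALT is
    a conflict (AMBIGUOUS); AMBIGUOUS dominates everything.
    """
    if AlleleCall.AMBIGUOUS in (c1, c2):
        return AlleleCall.AMBIGUOUS
    if c1 is AlleleCall.NONE:
        return c2
    if c2 is AlleleCall.NONE:
        return c1
    if c1 is c2:
        return c1
    return AlleleCall.AMBIGUOUS


@dataclass
class HaplotypeTable:
    """Counts of per-pair (site A, site B) allele configurations."""

    n_rr: int = 0
    n_ra: int = 0
    n_ar: int = 0
    n_aa: int = 0
    n_site_a_only: int = 0
    n_site_b_only: int = 0
    n_uninformative: int = 0
    n_conflict: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_dict().values()):
            raise ValueError("negative count in haplotype table")

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in
                ("n_rr", "n_ra", "n_ar", "n_aa",
                 "n_site_a_only", "n_site_b_only", "n_uninformative", "n_conflict")}

    @property
    def n_informative(self) -> int:
        return self.n_rr + self.n_ra + self.n_ar + self.n_aa

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())

    @property
    def cis_support(self) -> int:
        return self.n_rr + self.n_aa

    @property
    def trans_support(self) -> int:
        return self.n_ra + self.n_ar


_CELL = {
    (AlleleCall.REF, AlleleCall.REF): "n_rr",
    (AlleleCall.REF, AlleleCall.ALT): "n_ra",
    (AlleleCall.ALT, AlleleCall.REF): "n_ar",
    (AlleleCall.ALT, AlleleCall.ALT): "n_aa",
}


def tabulate(observations: Iterable[PairObservation]) -> HaplotypeTable:
    """Count each pair into exactly one table cell."""
    table = HaplotypeTable()
    for obs in observations:
        a, b = obs.call_a, obs.call_b
        if AlleleCall.AMBIGUOUS in (a, b):
            table.n_conflict += 1
        elif (a, b) in _CELL:
            setattr(table, _CELL[(a, b)], getattr(table, _CELL[(a, b)]) + 1)
        elif a is not AlleleCall.NONE:
            table.n_site_a_only += 1
        elif b is not AlleleCall.NONE:
            table.n_site_b_only += 1
        else:
            table.n_uninformative += 1
    return table


@dataclass(frozen=True)
class PhaseCall:
    configuration: Configuration
    support_fraction: Optional[float]
    p_value: Optional[float]
    table: HaplotypeTable

    def as_dict(self) -> dict:
        return {
            "configuration": self.configuration.value,
            "support_fraction": self.support_fraction,
            "p_value": self.p_value,
            **self.table.as_dict(),
            "n_informative": self.table.n_informative,
        }


def call_phase(table: HaplotypeTable, min_informative: int = 10,
               min_support_fraction: float = 0.9) -> PhaseCall:
    """Decide CIS / TRANS / AMBIGUOUS / INSUFFICIENT_DATA from the table.

    The p-value is the two-sided exact binomial probability of the
    observed minority count out of n_informative under a 0.5 null; it is
    reported, not used for the decision.
    """
    n = table.n_informative
    if n < min_informative:
        return PhaseCall(Configuration.INSUFFICIENT_DATA, None, None, table)
    cis, trans = table.cis_support, table.trans_support
    p_value = binomtest(min(cis, trans), n, 0.5).pvalue
    support = max(cis, trans) / n
    if support < min_support_fraction:
        configuration = Configuration.AMBIGUOUS
    elif cis > trans:
        configuration = Configuration.CIS
    elif trans > cis:
        configuration = Configuration.TRANS
    else:
        configuration = Configuration.AMBIGUOUS  # only when min_support_fraction <= 0.5
    return PhaseCall(configuration, support, p_value, table)


def summarize_run(raw_pair_count: int, table: HaplotypeTable,
                  site_counts: dict[str, dict[str, int]],
                  duplicates_removed: int = 0,
                  phase: Optional[PhaseCall] = None) -> dict:
    """Assemble the run-level report record.

    ``site_counts`` maps site label -> {"n_ref": ..., "n_alt": ...}
    (deduplicated pair counts per site, regardless of the other site).
    """
    kept = table.total
    informative_a = table.n_informative + table.n_site_a_only
    informative_b = table.n_informative + table.n_site_b_only
    per_site = {}
    for label, counts in site_counts.items():
        depth = counts["n_ref"] + counts["n_alt"]
        per_site[label] = {
            "n_ref": counts["n_ref"],
            "n_alt": counts["n_alt"],
            "alt_frequency": counts["n_alt"] / depth if depth else None,
        }
    record = {
        "total_pairs": raw_pair_count,
        "pairs_after_dedup": kept,
        "duplicates_removed": duplicates_removed,
        "pairs_informative_site_a": informative_a,
        "pairs_informative_site_b": informative_b,
        "pairs_informative_both": table.n_informative,
        "both_site_fraction": table.n_informative / kept if kept else 0.0,
        "conflict_pairs": table.n_conflict,
        "site_allele_counts": per_site,
        "haplotype_table": table.as_dict(),
    }
    if phase is not None:
        record["phase"] = phase.as_dict()
    return record
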