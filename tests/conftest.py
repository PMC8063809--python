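from __future__ import annotations

import pytest

from ampliphase.io import write_fasta, write_fastq_pairs
from ampliphase.pipeline import RunConfig, run_phase
from ampliphase.simulate import SimConfig, resolve_config, simulate_pairs
from ampliphase.variants import Variant


@pytest.fixture
def dup_variant() -> Variant:
    """Single-base duplication in a homopolymer run (frameshift-like)."""
    return Variant("chr13", 51958362, "G", "GG")


@pytest.fixture
def snv_variant() -> Variant:
    return Variant("chr13", 51964900, "C", "T")


# The two ~10-mer windows around the variant sites; the ref/alt contexts
# built from them are the pipeline's distinguishing k-mers.
DUP_WINDOW = "ATGGGGGGCG"      # run of six G, duplication of the final run base
DUP_WINDOW_OFFSET = 7          # 0-based offset of the final run G
SNV_WINDOW = "CCCGTGGACC"
SNV_WINDOW_OFFSET = 8


def run_sim_pipeline(cfg: SimConfig, tmp_path, **overrides):
    """Simulate reads, write FASTQ + reference, run the full pipeline."""
    resolved = resolve_config(cfg)
    pairs, truth = simulate_pairs(cfg)
    ref_path = tmp_path / "ref.fa"
    r1 = tmp_path / "r1.fastq"
    r2 = tmp_path / "r2.fastq"
    write_fasta({"amplicon": resolved.ref_amplicon}, ref_path)
    write_fastq_pairs(pairs, r1, r2)
    run_config = RunConfig(reference=str(ref_path), r1=str(r1), r2=str(r2),
                           variant_a=str(resolved.variant_a),
                           variant_b=str(resolved.variant_b),
                           umi_len=cfg.umi_len, **overrides)
    return run_phase(run_config), resolved, pairs, truth
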