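# ampliphase

Read-backed **cis/trans phasing** of two heterozygous variants from targeted
cDNA amplicon sequencing, with **allelic-expression** analysis, **UMI
deduplication**, and a built-in paired-end **read simulator** that provides
ground truth for every stage.

Two heterozygous variants in one gene may sit on the same allele (*in cis*,
one functional copy remains) or on opposite alleles (*in trans*, a compound
heterozygote). Because splicing collapses large genomic distances to short
mRNA distances, a short paired-end read pair over a targeted cDNA amplicon
can observe both variant sites at once. `ampliphase` types each read pair at
both sites by exact matching of short allele-distinguishing context k-mers
(no alignment or CIGAR parsing), collapses PCR duplicates by UMI, tabulates
the 2×2 haplotype configuration, and calls the phase. The same deduplicated
counts yield per-allele and per-haplotype expression fractions with an exact
binomial imbalance test (Clopper–Pearson 95% CI); a reduced mutant-allele
fraction at a truncating variant is consistent with nonsense-mediated decay.

## Modules

| module | purpose |
| --- | --- |
| `ampliphase.variants` | `Variant`, `TranscriptModel`, genomic/cDNA distance arithmetic, exon-model coordinate mapping |
| `ampliphase.contexts` | allele-distinguishing context k-mers (homopolymer-safe) and exact-match allele calling |
| `ampliphase.umi` | UMI extraction (`name_suffix` / `inline_prefix`) and duplicate collapsing (`exact` / `directional`) |
| `ampliphase.phasing` | mate-call merging, 2×2 configuration table, cis/trans call, run summary |
| `ampliphase.expression` | allele frequencies, exact binomial imbalance test, per-haplotype expression |
| `ampliphase.simulate` | deterministic paired-end simulator (amplicon vs fragmentation libraries, errors, UMIs, PCR duplication) with a per-pair truth table |
| `ampliphase.io` / `ampliphase.cli` / `ampliphase.pipeline` | FASTA/FASTQ/SAM/VCF/BED12 readers, TSV/JSON reports, the `ampliphase` command |

## CLI

```sh
# simulate a trans compound heterozygote (FASTQ R1/R2 + truth TSV + config echo)
ampliphase simulate --configuration TRANS --n-pairs 2000 --error-rate 0.01 \
    --seed 7 --out-prefix sim

# call phase (exit 0 on CIS/TRANS, 3 on ambiguous/insufficient, >=4 on error)
ampliphase phase --r1 sim_R1.fastq --r2 sim_R2.fastq --reference ref.fa \
    --variant-a amplicon:79:C:T --variant-b amplicon:542:G:GG --out-dir out

# allelic expression report for the same inputs
ampliphase ase --r1 sim_R1.fastq --r2 sim_R2.fastq --reference ref.fa \
    --variant-a amplicon:79:C:T --variant-b amplicon:542:G:GG --out-dir out

# show the allele-distinguishing k-mers for a variant
ampliphase contexts --reference ref.fa --variant amplicon:542:G:GG

# coordinate arithmetic: genomic distance (plain difference, kb rounded
# half-up to 1 decimal) and cDNA span (inclusive, |delta|+1)
ampliphase coords --variant-a chr13:51958362:G:GG --variant-b chr13:51964900:C:T \
    --cdna-a 2304 --cdna-b 1841
```

Variants are given as `CHROM:POS:REF:ALT` literals (1-based, `POS` within
the reference FASTA record); minimal VCF input is supported through the API
(`ampliphase.io.read_vcf_variants`). SAM/BAM input is used purely as a
read-pair container (`--alignment`); reverse-complement search is on by
default for FASTQ and off for SAM/BAM (`--both-strands` overrides).

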