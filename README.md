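# vntrkit

Alignment-free genotyping of a promoter VNTR (33-bp repeat unit) from
short-read sequencing data, with the downstream population-genetic and
expression-association analyses, and a synthetic-data generator so every
stage is testable without access-controlled cohort data.

Two complementary genotyping routes are implemented:

* **k-mer copy-number estimation** (`vntrkit.kmer_cn`) — estimates the
  diploid-average repeat copy number from unaligned reads as
  `median(repeat 25-mer counts) / max(median(5' flank counts), median(3' flank counts))`,
  with canonical (strand-agnostic) counting. Works at any read length.
* **spanning-read allele calling** (`vntrkit.span`) — calls discrete alleles
  from reads that fully span the repeat array plus 6 bp anchors on both
  flanks, at edit distance ≤ 2 (bit-parallel Myers matcher). Alleles too
  long to span (≥ 5 copies at 150 bp reads) are detected from partial
  coverage; a dedicated scan flags reads indicative of ≥ 6 copies. Per
  sample, alleles with < 2 supporting reads are dropped and samples with
  > 2 surviving alleles are excluded.

On top of the calls: allele frequencies and multi-allelic fixation index
`F_ST = (H_T − H_S)/H_T` (`vntrkit.popgen`), and copy-number–expression
correlation with BH FDR, per-tissue screens, SNP-dosage regression and
composite LD r² (`vntrkit.assoc`). `vntrkit.simulate` generates
Hardy–Weinberg cohorts, error-bearing reads from both haplotypes,
haplotype-linked SNPs and expression matrices with a single causal gene —
all bit-reproducible from a seed, with truth tables for recovery testing.

## CLI

All commands are subcommands of `vntrkit` (see `vntrkit --help`). A
locus is defined by a JSON config pointing at FASTA files for the repeat
unit and the two flanks:

```sh
vntrkit make-locus --seed 7 --out demo/locus          # synthetic demo locus
vntrkit simulate-cohort --n 50 --seed 1 --out demo/cohort
vntrkit simulate-reads --locus demo/locus/locus.json \
    --cohort demo/cohort/cohort_truth.tsv --out demo/reads
vntrkit kmer-genotype --locus demo/locus/locus.json --reads demo/reads/S0001.fastq
vntrkit span-genotype --locus demo/locus/locus.json --reads demo/reads/S0001.fastq
vntrkit run-pipeline --n 50 --seed 1 --out demo/run   # end-to-end demo
```

Other subcommands: `scan-six-plus`, `allele-freqs`, `fst`, `correlate`,
`tissue-screen`, `snp-effect`, `ld`. Inputs and outputs are plain TSV/JSON;
FASTQ may be gzipped; a BAM front-end (`vntrkit.io.extract_bam_region`)
extracts reads near the locus for the alignment-free callers.

The repository ships no real promoter sequence: the demo locus is random
(fixed seed) with the TT(G/A)CATCA regulatory motif at unit offset 13.
Users supply real sequences via FASTA + config.

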