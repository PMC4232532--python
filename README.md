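# divergekit

Divergence analysis of two inbred plant genotypes from deep RNA-seq, built
around the *Brassica rapa* setting: two varieties (parents of a mapping
population) are each aligned to a common reference genome (a third
genotype), and their between-genotype coding SNPs, molecular-evolution
signal, and novel transcripts are extracted from the alignments.

The package is aimed at researchers building gene-based marker systems or
re-annotating a genome from RNA-seq, and at anyone who needs the individual
pieces: trio-style SNP deduction, Nei–Gojobori Ka/Ks, stratified
permutation tests, or a transcript-triage cascade.

## What it computes

- **Per-genotype variant calling** from per-position allele-count tables
  ("genotype files": chrom, pos, sample, A, C, G, T). A site is called when
  depth ≥ 4 and the modal non-reference base reaches the purity cutoff
  (default 0.75) — inbred lines are effectively homozygous.
- **Trio deduction**: a genotype1-vs-genotype2 SNP is inferred where the two
  vs-reference call sets imply different alleles; a one-sided variant
  requires the counterpart to be covered (≥ 4 reads) and to match the
  reference. A **noise-reduction genotyping** step then re-interrogates both
  genotypes' counts at every putative SNP and keeps it only if a clear read
  majority (> 0.8 by default) supports each genotype's expected allele —
  this removes sites still segregating within a nominally inbred stock.
- **SNP effect annotation** against GFF3 gene models: intergenic / intronic /
  CDS / 5′UTR / 3′UTR, strand-aware codon position, synonymous vs
  nonsynonymous under the standard code; per-gene SNP rates
  (SNPs per 100 bp of gene) with a centred 25-gene rolling mean.
- **Ka/Ks** per gene from SNP-substituted genotype genomes: NG86
  (pathway-averaged Nei–Gojobori with Jukes–Cantor correction, verified
  against Biopython to 1e-9) and a Li–Wu–Luo (1985) transition/transversion
  variant. Chromosome-level inference uses a permutation test on the
  difference in median Ka/Ks between each chromosome and the rest of the
  genome (1000 permutations by default), optionally **stratified by the
  LF/MF1/MF2 sub-genomes** of the *Brassica* triplication so every permuted
  chromosome keeps its exact sub-genome composition.
- **Transcript triage**: redundant assembled transcripts are reduced to a
  novel set by exact-duplicate removal → per-locus representative selection
  → known-CDS matching (≥ 95% identity over ≥ 100 bp, k-mer-seeded edlib
  alignment) → exon-chain construction → chimera removal → >10 kb span
  filter → ≥ 50 aa ORF requirement → longest-isoform selection, with
  gffcompare-style class codes (`=`, `c`, `j`, `o`, `x`, `i`, `u`) and a
  per-stage survivor table.
- **Validation-rate arithmetic** for Sanger-validation panels (validation,
  false-positive, false-negative rates as integer percents).
- **Synthetic data**: every input above can be generated with known ground
  truth (genomes, gene models with sub-genome labels, planted variants,
  overdispersed noisy allele counts, redundant transcript sets), so the
  whole pipeline is testable without any downloads.

## Worked example

```python
from divergekit.simulate import (SimulationConfig, simulate_genome,
                                 plant_variants, simulate_allele_counts)
from divergekit.trio import trio_pipeline

cfg = SimulationConfig(seed=7)            # 10 chromosomes x 100 kb, ~100 genes,
genome, models = simulate_genome(cfg)     # coding SNPs at 1/120 bp, depth 30,
planted = plant_variants(genome, models, cfg)  # 1% per-base error
counts = {g: simulate_allele_counts(mut, models, truth, cfg, g)
          for g, (truth, mut) in planted.items()}
kept, audit = trio_pipeline(counts["G1"], counts["G2"], genome)
print(len(kept), audit.status.value_counts().to_dict())
```

prints

```
1041 {'kept': 1041, 'excluded_shared': 1}
```

i.e. 1041 between-genotype SNPs survive the call → deduce → noise-filter
cascade (every planted difference covered by ≥ 4 reads in both genotypes,
with no false calls), and one site where both genotypes carry the same
alternate allele is correctly excluded as shared divergence from the
reference rather than a between-genotype SNP.

The same pipeline is available from the shell:

```bash
divergekit simulate --out sim --seed 7
divergekit trio --counts sim/allele_counts.tsv --ref sim/reference.fa \
    --g1 G1 --g2 G2 --out-vcf trio.vcf --out-audit audit.tsv
divergekit annotate --vcf trio.vcf --gff sim/genes.gff3 \
    --ref sim/reference.fa --out-effects effects.tsv --out-rates rates.tsv
divergekit kaks --vcf trio.vcf --ref sim/reference.fa --gff sim/genes.gff3 \
    --g1 G1 --g2 G2 --out kaks.tsv
divergekit kaks-permute --table kaks.tsv --mode subgenome --seed 1 --out perm.tsv
```

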