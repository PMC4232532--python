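# Methods

This note documents the models and procedures implemented in divergekit,
the defaults and why they are set where they are, and what the synthetic
data does and does not emulate.

## Study design being modelled

Two inbred genotypes (think of the *Brassica rapa* parents of a
recombinant-inbred mapping population) are deeply RNA-sequenced and each
aligned to the reference genome of a third genotype. Between-genotype SNPs
are deduced by comparing the two vs-reference variant lists ("trio"
deduction), annotated against the gene models, used to build per-genotype
genome sequences for Ka/Ks estimation, and — separately — assembled
transcripts are triaged into a novel set to update the annotation.
Upstream read processing, alignment, deduplication, and assembly are out of
scope; the pipeline starts from per-position allele counts and from
assembled transcript sequences with genome-alignment segments.

## Variant calling and trio deduction

A per-genotype call at a site requires depth ≥ `min_depth` (default 4
reads, the coverage floor used throughout, including for the counterpart
check) and modal non-reference base fraction ≥ `min_alt_fraction`. Only the
modal alternate is considered (inbred lines; ties break alphabetically and
are logged). Sites with an ambiguous reference base (N) are skipped with a
log entry.

Trio deduction emits, per candidate site, one of five outcomes: one-sided
variant with a covered reference-matching counterpart (putative), the
mirror case, both-called-different (putative), both-called-same
(excluded_shared), or insufficient counterpart coverage
(excluded_coverage). A counterpart that is uncalled yet modally
non-reference is recorded as filtered_noise — a mixed pileup is precisely
the signal the noise filter exists to remove, and the status enum keeps
that interpretation.

The noise-reduction step recounts, at every putative SNP, the reads
matching each genotype's expected allele against all other reads, and
keeps the SNP only when `match_fraction > majority_threshold` on **both**
sides.

### Threshold calibration

The two fraction cutoffs are set by a separation argument rather than by
convention. The calling cutoff must accept a fixed allele read at ~99%
(1% per-base error) and reject a 50/50 segregating mixture; the noise
majority must do the same at the scoring stage. Under the generator's
default depth model (negative binomial, mean 30, size 60) the per-site
error probabilities are, analytically:

- calling at 0.75: a miss requires an error load above a quarter of the
  reads — probability ≈ 1e-6 per site; a 50/50 site reaches 0.75 purity
  with probability ≈ 3e-3, and when it does the trio comparison discards
  it as a shared allele, so the event is harmless. A 0.9 cutoff, by
  contrast, loses ~1–3 sites per thousand at depths in the twenties
  (alt fraction ≥ 0.9 tolerates only floor(0.1·d) errors), which is why it
  is not the default.
- noise majority at 0.8 (a 4:1 read majority): a true site fails with
  probability ≈ 1e-5; a 50/50 site passes with probability ≈ 1e-3. A bare
  > 0.5 majority would pass half of all 50/50 sites (binomial sampling
  around its own mean), defeating the filter's purpose.

Both cutoffs are configurable; the defaults make exact truth recovery the
expected outcome on the synthetic study system (expected total failures
≈ 0.07 per full run), while a residual ~5% chance of a single leaked or
missed site per run is inherent to the binomial tails and is reported
honestly when it occurs.

## SNP effects and rates

Region classification is by interval membership with precedence CDS > UTR >
intron inside a gene, and any gene overlap beating intergenic. 5′/3′ UTRs
are derived from exon-minus-CDS geometry by strand. For CDS SNPs of models
whose total CDS length is divisible by 3, the codon is extracted
strand-aware from the spliced CDS and translated with the standard code;
incomplete models yield a CDS region with codon fields omitted. A SNP in
overlapping genes gets one effect per gene plus a designated most-severe
effect (CDS-nonsynonymous > CDS-synonymous > UTR > intron) for single-count
summaries.

Per-gene SNP rates are 100 × count / gene length, with gene length taken as
genomic span (start..end) by default ("exonic" is available); the rolling
mean is a centred 25-gene window that shrinks at edges and never crosses a
chromosome boundary.

## Ka/Ks

Genotype genomes are built by substituting each genotype's SNPs into the
reference; CDS pairs are then extracted by the same strand-aware splicing,
so the pair is aligned by construction (no alignment step, no indels).
Pairs with incomplete models or internal stop codons are skipped and
logged.

**NG86 (default).** Synonymous sites per codon are the fraction of the nine
single-base neighbour mutations that preserve the amino acid (mutations to
stop codons count as nonsynonymous), times three, averaged over the two
sequences. Codon differences are resolved by averaging syn/nonsyn step
counts over all minimal mutational pathways; a stop→stop step is
synonymous, steps into or out of a stop are nonsynonymous. pN = Nd/N and
pS = Sd/S receive the Jukes–Cantor correction K = −(3/4)·ln(1 − 4p/3),
undefined at p ≥ 3/4 (the record is flagged). Stop codons and codons with
ambiguous bases are excluded from both site and difference counting in both
sequences, so N + S equals the aligned non-stop length. This implementation
agrees with Biopython's independent NG86 (`Bio.codonalign`) to 1e-9 on
random codon pairs, which the test suite asserts.

**Weighted variant.** `method="weighted"` takes Ka and Ks from the
Li–Wu–Luo (1985) estimator: each codon position is classed as 0-, 2-, or
4-fold degenerate; transitional (P) and transversional (Q) difference
proportions per class receive Kimura two-parameter components
A = ½ln(1/(1−2P−Q)) − ¼ln(1/(1−2Q)) and B = ½ln(1/(1−2Q)); then
Ks = 3[L₂A₂ + L₄(A₄+B₄)]/(L₂+3L₄) and Ka = 3[L₂B₂ + L₀(A₀+B₀)]/(2L₂+3L₀).
This is the transition/transversion-aware family the MLWL estimator
belongs to; exact MLWL replication is a non-goal since chromosome-level
conclusions rest on relative, not absolute, values. (A literal "weight the
NG86 pathways by transition content" scheme is a no-op — every minimal
pathway between two codons contains the same multiset of base changes — so
it was not implemented.)

Genes with Ks = 0 or a diverged correction have an undefined ratio and are
excluded from medians, with a log entry.

**Sub-genome comparison.** Per-label (LF/MF1/MF2) medians plus pairwise
two-sided permutation tests on the median difference (default 10,000 label
shuffles, seeded); p = (1 + #{|null| ≥ |obs|}) / (n + 1).

**Chromosome permutation test.** The statistic is median Ka/Ks of a
chromosome minus the median of the rest of the genome. The null reassigns
genes to chromosomes at random keeping per-chromosome gene counts
(unconstrained mode) or reassigns within each sub-genome label so every
chromosome keeps its exact LF/MF1/MF2 composition (constrained mode). A
chromosome is significant when |observed| ≥ |null| in at least 95% of
permutations, ties counting as exceeded (with n_perm = 200 this realises a
type-I rate of ≈ 11/201 ≈ 5.5%, inside the calibration band the tests
assert). Chromosomes with fewer than two defined ratios are excluded with a
warning. Permutations are vectorised (one shuffled matrix per test), so 200
replicates of a 10-chromosome, 500-gene null study run in seconds.

## Transcript triage

The cascade runs in a fixed order, and every input transcript ends in
exactly one terminal disposition (duplicate, non_representative, known,
unplaced, chimera, over_span, no_orf, isoform_dropped, novel):

1. byte-identical duplicate removal (first id kept);
2. one representative per assembler locus by (coverage, length, id);
3. known-CDS matching: candidate pairs seeded by shared 15-mers in either
   orientation, verified by an edlib infix alignment of the shorter
   sequence in the longer; known iff identity ≥ 0.95 over ≥ 100 aligned
   bases (the aligned-length floor replaces an e-value gate —
   deterministic and database-free);
4. transcripts without genome segments go to an "unplaced" bin rather than
   being silently dropped;
5. exon chains are built by merging overlapping/adjacent same-chromosome
   segments (BED, 0-based half-open);
6. chimera removal: substantial exons (≥ 50 bp) on two or more
   chromosomes; same-chromosome distant hits are not chimeric — they fall
   to the span filter;
7. span filter: genomic span (max end − min start) strictly greater than
   10 kb is removed, exactly 10 kb is retained;
8. ORF requirement: at least one complete start-to-stop ORF of ≥ 50 aa
   (Met included) on either strand; for each stop codon in each frame the
   ORF starts at the first upstream ATG, and the primary ORF is the
   longest (the published pipelines pick the ORF with the most database
   hits, which needs an external database; longest is the deterministic
   stand-in);
9. longest isoform per genomic locus (connected components of exon-chain
   overlap), ties to the smallest id, logged.

Class codes follow the gffcompare vocabulary with precedence
`=` (identical intron chain) > `c` (contained) > `j` (shares some but not
all junctions) > `o` (same-strand exonic overlap, no shared junction) >
`x` (opposite-strand exonic overlap) > `i` (entirely inside a reference
intron) > `u` (no gene overlap). The codes `e`, `p`, `s` require
pre-mRNA/run-on heuristics with no operational definition here; inputs
that would receive them fall into `o`/`u` by precedence.

## Validation arithmetic

With n detected SNPs across validated regions, n₀ without usable Sanger
data, and c confirmed: validation rate (with data) = c/(n−n₀), its
complement is the with-data false-positive rate, overall rate = c/n,
overall FP = (n−n₀−c)/n, unknown = n₀/n. The false-negative rate among m
Sanger-discovered SNPs is missed/(called+missed), i.e. restricted to
adequately covered positions. All rates are integer percents rounded
half-up (implemented in exact integer arithmetic); the published tables
(202/32/158 → 93/7/78/6/16%; 193/158/29/6 → 4%) are consistent with this
rule, which the tests pin down.

## Synthetic data

`simulate_genome` packs genes (ATG + random sense codons + stop, UTRs,
optional introns, explicit strand) left-to-right with random intergenic
gaps, round-robin over chromosomes; sub-genome labels are drawn i.i.d. from
`subgenome_props` (default 0.6/0.25/0.15, LF-dominant as in the triplicated
*Brassica* gene complement). `plant_variants` plants coding SNPs at
`snp_rate_coding` (default 1/120 bp, the observed genotype-vs-reference
coding rate) and noncoding SNPs at 1/200 bp; coding alternates are chosen
codon-aware against the codon's current state, so multiple hits in one
codon cannot combine into a stop or break a forced-synonymy guarantee
(`synonymous_bias` forces that fraction of coding variants to be
synonymous; positions without a synonymous alternative are redrawn).
Terminal stop codons are never mutated.

Residual heterogeneity (`het_fraction`) plants, in each genotype, a shared
alternate allele at that fraction of the counterpart's variant sites,
marked `het`: the consensus haplotype carries the alternate but the read
counts emit a 50/50 mixture. This is the configuration that actually
generates apparent false positives in a trio design — fixed in one
genotype, still segregating in the other — and the only one that produces
putative SNPs for the noise filter to remove; a site heterogeneous on a
genotype's own private variant never survives calling in the first place.

`simulate_allele_counts` draws one depth per gene from a negative binomial
(mean `mean_depth` = 30, size `depth_dispersion` = 60 — mildly
overdispersed), applies it uniformly over the gene's exonic positions, and
emits multinomial base counts with per-read error `error_rate` (uniform
over the three other bases). Intergenic/intronic depth is 0 (RNA-seq);
`background_depth` adds shallow Poisson genomic coverage for
false-negative studies, mimicking Sanger-only SNPs falling below the
RNA-seq coverage threshold.

`simulate_transcript_set` fabricates one transcript set per triage
disposition: exact spliced copies of annotated genes, byte-identical
duplicates, lower-coverage locus-mates, pure-CDS fragments, intergenic
novels with planted ≥ 50 aa ORFs (single- and two-exon), shorter isoforms
of some novels, cross-chromosome chimeras, a > 10 kb-span artifact,
ORF-less transcripts (drawn from {A,C,G}, so no ATG on either strand), and
an unplaced transcript. Genome mapping is an *input* to triage, so
fabricated loci carry synthetic sequences with fabricated intergenic
segment coordinates; triage never re-aligns sequence to genome.

All randomness derives from `numpy.random.default_rng([seed, stream])`
with one stream per generator stage: a fixed seed gives byte-identical
outputs, and stages are independently reproducible.

### What passing tests do and do not show

The generator emulates the *statistical* structure of the study — coverage
thresholds, error loads, residual heterogeneity, sub-genome composition,
transcript redundancy classes — not real data. It omits alignment and
mapping artifacts (multi-mapping, reference bias, splice-junction errors),
indels and structural variants, strand-specific coverage, quality scores,
position-dependent error profiles, paralog collapse in the triplicated
genome, and the orders-of-magnitude expression dispersion of real RNA-seq
(the default NB size of 60 is far tamer). Exact truth recovery on this
system validates the pipeline's logic and thresholds, not its performance
on real alignments, where the upstream artifacts dominate the error
budget. Likewise, genome-scale counts from the original study
(hundreds of thousands of SNPs, thousands of novel transcripts,
per-chromosome permutation percentages) depend on the real genome and
reads and are not reproduced at this scale.

## Problem sizes

The test suite and `scripts/acceptance.py` use: a 10 × 100 kb genome with
~100 genes (~1,000–1,100 covered between-genotype differences) for pipeline
recovery; 1,000 planted CDS SNPs for the annotation oracle; 500 genes of
200 codons at 3% divergence for the neutral Ka/Ks calibration; 200
replicate null/shifted studies at 200 permutations each for permutation
calibration and power; and a 31-transcript redundant set for triage. These
sizes give tight Monte-Carlo error on every asserted quantity while the
whole suite runs in well under a minute per module.
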