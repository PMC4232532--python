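"""Synthetic genomes, planted variants, noisy allele counts, and transcripts.

This module generates the study system end to end with known ground truth:
a small multi-chromosome genome with protein-coding gene models labelled by
sub-genome (LF/MF1/MF2), two inbred genotypes diverged from the reference at
configurable coding/noncoding SNP rates (with an optional residually
segregating fraction), RNA-seq-like per-position allele counts with
overdispersed gene-level depth and per-base miscalls, and redundant
transcript sets covering every disposition the triage cascade must handle.

Every generator takes its randomness from the config seed via
``numpy.random.default_rng([seed, stream])`` so a fixed seed yields
byte-identical outputs while the individual stages stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SizingError
from .models import GeneModel
from .seq import BASES, CODON_TABLE, SENSE_CODONS, STOP_CODONS, extract_spliced, revcomp

SUBGENOMES = ("LF", "MF1", "MF2")

# rng stream ids, one per generator stage
_STREAM_GENOME = 0
_STREAM_VARIANTS = 1
_STREAM_COUNTS = 2
_STREAM_TRANSCRIPTS = 3
_STREAM_KAKS = 4

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study system.

    Rates are per base pair; ``depth_dispersion`` is the negative-binomial
    size parameter k in the mean-variance form var = mu + mu^2/k (larger k =
    closer to Poisson). ``het_fraction`` controls residual heterogeneity:
    each genotype receives, at that fraction of the counterpart genotype's
    variant sites, a shared alternate allele that is still segregating in
    its own stock and therefore emits a 50/50 allele mixture in the read
    counts (see :func:`plant_variants`).
    """

    n_chromosomes: int = 10
    chrom_length: int = 100_000
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (1, 4)
    cds_codons: tuple[int, int] = (80, 280)
    utr_length: tuple[int, int] = (30, 150)
    intron_length: tuple[int, int] = (60, 200)
    intergenic_gap: tuple[int, int] = (200, 2000)
    snp_rate_coding: float = 1 / 120
    snp_rate_noncoding: float = 1 / 200
    synonymous_bias: float = 0.0
    error_rate: float = 0.01
    mean_depth: float = 30.0
    depth_dispersion: float = 60.0
    background_depth: float = 0.0
    het_fraction: float = 0.0
    subgenome_props: tuple[float, float, float] = (0.6, 0.25, 0.15)
    genotypes: tuple[str, str] = ("G1", "G2")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate_coding", "snp_rate_noncoding", "synonymous_bias",
                     "error_rate", "het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.subgenome_props) - 1.0) > 1e-9:
            raise ValueError("subgenome_props must sum to 1")
        if self.error_rate >= 0.25:
            raise ValueError("error_rate must be < 0.25 (miscalls are uniform "
                             "over the three other bases)")

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *extra])


# --------------------------------------------------------------------------
# genome + gene models
# --------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; no internal stops by construction."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = sorted(STOP_CODONS)[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` positive integers, uniformly at random."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a reference genome and its gene models.

    Genes are packed left to right on each chromosome, round-robin across
    chromosomes, with random intergenic gaps. Each gene has a start codon,
    random sense codons, a stop codon, UTRs on both ends, and optional
    introns; total CDS length is divisible by 3 by construction.

    Raises :class:`SizingError` when the requested genes do not fit.
    """
    rng = config.rng(_STREAM_GENOME)
    chroms = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chrom_arrays = {
        c: rng.integers(0, 4, size=config.chrom_length).astype(np.uint8)
        for c in chroms
    }
    cursors = {c: 0 for c in chroms}  # 0-based index of next free position
    models: list[GeneModel] = []
    labels = rng.choice(len(SUBGENOMES), size=config.n_genes,
                        p=list(config.subgenome_props))

    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        utr_a = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
        utr_b = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        cds_seq = _random_cds(rng, n_codons)
        chunks = _split_lengths(rng, len(cds_seq), n_exons)
        introns = [int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                   for _ in range(n_exons - 1)]

        start = cursors[chrom] + gap + 1  # 1-based gene start
        # genomic layout left->right: [utr_a][chunk1]<intron>[chunk2]...[utr_b]
        pos = start
        exons, cds = [], []
        for i, chunk in enumerate(chunks):
            ex_start = pos
            if i == 0:
                pos += utr_a
            cds.append((pos, pos + chunk - 1))
            pos += chunk
            if i == n_exons - 1:
                pos += utr_b
            exons.append((ex_start, pos - 1))
            if i < n_exons - 1:
                pos += introns[i]
        gene_end = exons[-1][1]
        if gene_end > config.chrom_length:
            raise SizingError(
                f"gene {gi} does not fit on {chrom}: needs up to position "
                f"{gene_end} of {config.chrom_length}"
            )
        cursors[chrom] = gene_end

        # write the CDS into the chromosome, strand-aware
        genomic_cds = cds_seq if strand == "+" else revcomp(cds_seq)
        arr = chrom_arrays[chrom]
        off = 0
        for s, e in cds:
            seg = genomic_cds[off:off + (e - s + 1)]
            arr[s - 1:e] = [BASES.index(b) for b in seg]
            off += e - s + 1

        models.append(GeneModel(
            gene_id=f"gene{gi + 1:04d}", chrom=chrom, strand=strand,
            exons=exons, cds=cds, subgenome=SUBGENOMES[labels[gi]],
        ))

    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    genome = {c: lut[a].tobytes().decode() for c, a in chrom_arrays.items()}
    return genome, sorted(models, key=lambda m: (m.chrom, m.start))


# --------------------------------------------------------------------------
# planted variants
# --------------------------------------------------------------------------

@dataclass
class _CodingIndex:
    chrom: np.ndarray      # per coding position, chromosome name
    pos: np.ndarray        # 1-based genomic position
    gene_idx: np.ndarray   # index into models
    cds_off: np.ndarray    # 0-based offset in the spliced CDS
    cds_seqs: list[str]    # per gene, spliced reference CDS


def _coding_index(genome: dict[str, str], models: list[GeneModel]) -> _CodingIndex:
    """Enumerate mutable coding positions (terminal stop codon excluded)."""
    chrom_l, pos_l, gene_l, off_l, seqs = [], [], [], [], []
    for gi, m in enumerate(models):
        seqs.append(extract_spliced(genome, m.chrom, m.cds, m.strand))
        if m.incomplete:
            continue
        cds_len = m.cds_len
        ivs = m.cds if m.strand == "+" else list(reversed(m.cds))
        off = 0
        for s, e in ivs:
            n = e - s + 1
            if m.strand == "+":
                positions = np.arange(s, e + 1)
                offsets = np.arange(off, off + n)
            else:
                positions = np.arange(e, s - 1, -1)
                offsets = np.arange(off, off + n)
            keep = offsets < cds_len - 3  # skip the stop codon
            chrom_l.append(np.repeat(m.chrom, keep.sum()))
            pos_l.append(positions[keep])
            gene_l.append(np.repeat(gi, keep.sum()))
            off_l.append(offsets[keep])
            off += n
    return _CodingIndex(
        chrom=np.concatenate(chrom_l) if chrom_l else np.array([], dtype=object),
        pos=np.concatenate(pos_l) if pos_l else np.array([], dtype=int),
        gene_idx=np.concatenate(gene_l) if gene_l else np.array([], dtype=int),
        cds_off=np.concatenate(off_l) if off_l else np.array([], dtype=int),
        cds_seqs=seqs,
    )


def _codon_alternatives(codon: str, cp: int, strand: str
                        ) -> tuple[str, list[tuple[str, bool, bool, str]]]:
    """Alternatives at codon position ``cp`` of the (possibly already
    mutated) codon: (ref_base, [(alt, synonymous, is_stop, new_codon)]).

    Bases are genomic (forward-strand); synonymy is evaluated on the spliced
    CDS, complementing for minus-strand genes. Evaluating against the
    current codon state rather than the reference codon keeps multiple
    variants in one codon from interacting (two individually synonymous
    changes can otherwise be jointly nonsynonymous, or create a stop).
    """
    ref_cds_base = codon[cp]
    ref_gen = ref_cds_base if strand == "+" else _COMPLEMENT[ref_cds_base]
    out = []
    for alt_gen in BASES:
        if alt_gen == ref_gen:
            continue
        alt_cds = alt_gen if strand == "+" else _COMPLEMENT[alt_gen]
        new_codon = codon[:cp] + alt_cds + codon[cp + 1:]
        out.append((
            alt_gen,
            CODON_TABLE[new_codon] == CODON_TABLE[codon],
            new_codon in STOP_CODONS,
            new_codon,
        ))
    return ref_gen, out


TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "zygosity", "region", "gene_id"]


def plant_variants(genome: dict[str, str], models: list[GeneModel],
                   config: SimulationConfig
                   ) -> dict[str, tuple[pd.DataFrame, dict[str, str]]]:
    """Plant per-genotype SNPs and build the mutated genotype genomes.

    Returns ``{genotype: (truth_table, mutated_genome)}``. Coding variants are
    drawn from CDS positions (terminal stop codons excluded) at
    ``snp_rate_coding``; with probability ``synonymous_bias`` a variant is
    forced synonymous (positions without a synonymous alternative are
    re-drawn). Alternatives that would create a premature stop codon are never
    planted, so every mutated CDS stays translatable. Noncoding variants are
    uniform over all non-CDS positions at ``snp_rate_noncoding``.

    Residual heterogeneity: each genotype additionally receives, at a
    ``het_fraction`` of the counterpart genotype's variant sites, a shared
    alternate allele that is still segregating in its own stock (zygosity
    ``het``). Such sites are not true between-genotype differences but
    produce 50/50 read mixtures in one genotype.
    """
    cindex = _coding_index(genome, models)
    n_coding = len(cindex.pos)
    coding_keys = set(zip(cindex.chrom.tolist(), cindex.pos.tolist()))
    cds_pos_by_chrom: dict[str, set[int]] = {}
    for m in models:
        s = cds_pos_by_chrom.setdefault(m.chrom, set())
        for a, b in m.cds:
            s.update(range(a, b + 1))

    planted_rows: dict[str, list[tuple]] = {}
    for g_i, genotype in enumerate(config.genotypes):
        rng = config.rng(_STREAM_VARIANTS, g_i)
        rows: list[tuple] = []
        used: set[int] = set()

        n_cod = rng.binomial(n_coding, config.snp_rate_coding) if n_coding else 0
        drawn = 0
        codon_state: dict[tuple[int, int], str] = {}  # (gene_idx, codon_idx)
        while drawn < n_cod and len(used) < n_coding:
            i = int(rng.integers(n_coding))
            if i in used:
                continue
            gi = int(cindex.gene_idx[i])
            m = models[gi]
            ci, cp = divmod(int(cindex.cds_off[i]), 3)
            cds_seq = cindex.cds_seqs[gi]
            codon = codon_state.get((gi, ci), cds_seq[3 * ci:3 * ci + 3])
            ref, alts = _codon_alternatives(codon, cp, m.strand)
            force_syn = rng.random() < config.synonymous_bias
            if force_syn:
                pool = [(a, nc) for a, syn, stop, nc in alts if syn and not stop]
            else:
                pool = [(a, nc) for a, syn, stop, nc in alts if not stop]
            if not pool:
                continue  # e.g. no synonymous alternative here; redraw
            used.add(i)
            drawn += 1
            alt, new_codon = pool[int(rng.integers(len(pool)))]
            codon_state[(gi, ci)] = new_codon
            # truth records the reference-genome base, which equals the
            # current-state base here because each position is drawn once
            rows.append((str(cindex.chrom[i]), int(cindex.pos[i]), ref, alt,
                         "coding", m.gene_id))

        # noncoding: everything outside CDS
        for chrom, seq in genome.items():
            cds_set = cds_pos_by_chrom.get(chrom, set())
            n_nc = len(seq) - len(cds_set)
            k = rng.binomial(n_nc, config.snp_rate_noncoding) if n_nc else 0
            if k == 0:
                continue
            noncoding = np.setdiff1d(
                np.arange(1, len(seq) + 1),
                np.fromiter(cds_set, dtype=int) if cds_set else np.array([], dtype=int),
            )
            picks = rng.choice(noncoding, size=k, replace=False)
            for p in np.sort(picks):
                ref = seq[p - 1]
                alt = [b for b in BASES if b != ref][int(rng.integers(3))]
                rows.append((chrom, int(p), ref, alt, "noncoding", ""))

        planted_rows[genotype] = rows

    # Residual heterogeneity: a het_fraction of the counterpart genotype's
    # variant sites are still segregating ref/alt in this genotype's stock
    # (shared ancestral polymorphism). The consensus haplotype carries the
    # alternate, so such a site is not a true between-genotype difference,
    # but its read counts will be a 50/50 mixture -- the configuration the
    # trio noise filter exists to remove.
    g1, g2 = config.genotypes
    het_extra: dict[str, list[tuple]] = {g1: [], g2: []}
    if config.het_fraction > 0:
        for me, other in ((g1, g2), (g2, g1)):
            rng = config.rng(_STREAM_VARIANTS, 10 + list(config.genotypes).index(me))
            mine = {(c, p) for c, p, *_ in planted_rows[me]}
            candidates = [row for row in planted_rows[other]
                          if (row[0], row[1]) not in mine]
            pick = rng.random(len(candidates)) < config.het_fraction
            het_extra[me] = [row for row, keep in zip(candidates, pick) if keep]

    result = {}
    for genotype in config.genotypes:
        rows = [(c, p, r, a, "hom", reg, gid)
                for c, p, r, a, reg, gid in planted_rows[genotype]]
        rows += [(c, p, r, a, "het", reg, gid)
                 for c, p, r, a, reg, gid in het_extra[genotype]]
        truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).sort_values(
            ["chrom", "pos"], ignore_index=True)
        mutated = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
                   for c, s in genome.items()}
        for c, p, a in zip(truth["chrom"], truth["pos"], truth["alt"]):
            mutated[c][p - 1] = ord(a)
        result[genotype] = (truth, {c: a.tobytes().decode() for c, a in mutated.items()})
    return result


def genome_diffs(ref: dict[str, str], other: dict[str, str]) -> pd.DataFrame:
    """All positions where two genome sequence sets differ (1-based)."""
    rows = []
    for chrom in ref:
        a = np.frombuffer(ref[chrom].encode(), dtype=np.uint8)
        b = np.frombuffer(other[chrom].encode(), dtype=np.uint8)
        for p in np.nonzero(a != b)[0]:
            rows.append((chrom, int(p) + 1, chr(a[p]), chr(b[p])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def between_genotype_truth(truth1: pd.DataFrame, truth2: pd.DataFrame) -> pd.DataFrame:
    """Planted sites where the two genotype alleles differ.

    At a site planted in only one genotype, the other genotype carries the
    reference base. Rows carry both zygosities (``hom`` for unplanted sides).
    """
    t1 = truth1.set_index(["chrom", "pos"])
    t2 = truth2.set_index(["chrom", "pos"])
    keys = sorted(set(t1.index) | set(t2.index))
    rows = []
    for key in keys:
        r1 = t1.loc[key] if key in t1.index else None
        r2 = t2.loc[key] if key in t2.index else None
        ref = (r1 if r1 is not None else r2)["ref"]
        a1 = r1["alt"] if r1 is not None else ref
        a2 = r2["alt"] if r2 is not None else ref
        if a1 == a2:
            continue
        rows.append((key[0], key[1], ref, a1, a2,
                     r1["zygosity"] if r1 is not None else "hom",
                     r2["zygosity"] if r2 is not None else "hom"))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "allele_g1", "allele_g2",
                       "zygosity_g1", "zygosity_g2"],
    )


# --------------------------------------------------------------------------
# allele counts
# --------------------------------------------------------------------------

def simulate_allele_counts(genotype_genome: dict[str, str], models: list[GeneModel],
                           truth: pd.DataFrame, config: SimulationConfig,
                           sample: str) -> pd.DataFrame:
    """RNA-seq-like per-position base counts for one genotype.

    Depth is drawn once per gene from NB(mean_depth, depth_dispersion) and
    applied uniformly to the gene's exonic positions (transcript-level
    expression); intergenic/intronic depth is 0 unless ``background_depth``
    adds shallow Poisson genomic coverage. Each read reports the genotype
    base with probability 1 - error_rate, otherwise a uniform other base;
    residually segregating (het) sites emit a 50/50 reference/alternate
    mixture before errors.
    """
    sample_idx = list(config.genotypes).index(sample) if sample in config.genotypes else 99
    rng = config.rng(_STREAM_COUNTS, sample_idx)
    e = config.error_rate
    het_sites = {
        (c, p): (r, a)
        for c, p, r, a, z in zip(truth["chrom"], truth["pos"], truth["ref"],
                                 truth["alt"], truth["zygosity"])
        if z == "het"
    }

    chroms_l, pos_l, depth_l, pvals_l = [], [], [], []

    def emit(chrom: str, positions: np.ndarray, depths: np.ndarray) -> None:
        seq = genotype_genome[chrom]
        base_idx = np.array([BASES.index(seq[p - 1]) for p in positions])
        pv = np.full((len(positions), 4), e / 3)
        pv[np.arange(len(positions)), base_idx] = 1 - e
        for j, p in enumerate(positions):
            het = het_sites.get((chrom, int(p)))
            if het is not None:
                ref_i, alt_i = BASES.index(het[0]), BASES.index(het[1])
                pv[j] = e / 3
                pv[j, ref_i] = 0.5 * (1 - e) + 0.5 * e / 3
                pv[j, alt_i] = 0.5 * (1 - e) + 0.5 * e / 3
        chroms_l.append(np.repeat(chrom, len(positions)))
        pos_l.append(positions)
        depth_l.append(depths)
        pvals_l.append(pv)

    mu, k = config.mean_depth, config.depth_dispersion
    if mu > 0:
        for m in models:
            depth = int(rng.negative_binomial(k, k / (k + mu)))
            if depth == 0:
                continue
            positions = np.concatenate([np.arange(s, e_ + 1) for s, e_ in m.exons])
            emit(m.chrom, positions, np.full(len(positions), depth))

    if config.background_depth > 0:
        exonic: dict[str, set[int]] = {}
        for m in models:
            s = exonic.setdefault(m.chrom, set())
            for a, b in m.exons:
                s.update(range(a, b + 1))
        for chrom, seq in genotype_genome.items():
            allpos = np.arange(1, len(seq) + 1)
            mask = ~np.isin(allpos, np.fromiter(exonic.get(chrom, ()), dtype=int))
            positions = allpos[mask]
            depths = rng.poisson(config.background_depth, size=len(positions))
            keep = depths > 0
            if keep.any():
                emit(chrom, positions[keep], depths[keep])

    if not chroms_l:
        return pd.DataFrame(columns=["chrom", "pos", "sample", "A", "C", "G", "T"])

    depth_all = np.concatenate(depth_l)
    pvals_all = np.concatenate(pvals_l)
    counts = rng.multinomial(depth_all, pvals_all)
    df = pd.DataFrame({
        "chrom": np.concatenate(chroms_l),
        "pos": np.concatenate(pos_l).astype(int),
        "sample": sample,
        "A": counts[:, 0], "C": counts[:, 1], "G": counts[:, 2], "T": counts[:, 3],
    })
    return df.sort_values(["chrom", "pos"], ignore_index=True)


# --------------------------------------------------------------------------
# transcript sets for the triage cascade
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptSimParams:
    """How many transcripts of each intended disposition to emit."""

    n_exact: int = 5
    n_duplicate: int = 2        # byte-identical copies of exact transcripts
    n_redundant: int = 2        # same assembler locus, lower coverage
    n_fragment: int = 3         # truncated pieces of annotated transcripts
    n_novel: int = 10           # intended survivors (intergenic, ORF-bearing)
    n_novel_isoform: int = 2    # shorter isoforms of the first novels
    n_chimera: int = 3          # segments on two chromosomes
    n_long: int = 1             # genomic span > 10 kb
    n_orfless: int = 2          # no ORF on either strand
    n_unplaced: int = 1         # no genome segments at all


@dataclass
class SimulatedTranscript:
    transcript_id: str
    sequence: str
    locus: str
    coverage: float
    segments: list[tuple[str, int, int, str]]  # (chrom, start, end, strand), BED
    intended_class: str


def _seg_rows(t: SimulatedTranscript) -> list[tuple]:
    return [(c, s, e, t.transcript_id, 0, st) for c, s, e, st in t.segments]


def simulate_transcript_set(genome: dict[str, str], models: list[GeneModel],
                            config: SimulationConfig,
                            params: TranscriptSimParams | None = None
                            ) -> tuple[list[SimulatedTranscript], pd.DataFrame, pd.DataFrame]:
    """Emit a redundant transcript set with known intended dispositions.

    Returns ``(transcripts, segments_bed, truth)`` where ``segments_bed`` is a
    BED6 DataFrame (0-based half-open) and ``truth`` maps each transcript id
    to its intended class. Genome mapping is an input to triage, not a step of
    it, so fabricated loci (novels, chimeras, the over-span artifact) carry
    synthetic sequences with fabricated segment coordinates in intergenic
    space.
    """
    params = params or TranscriptSimParams()
    rng = config.rng(_STREAM_TRANSCRIPTS)
    out: list[SimulatedTranscript] = []

    def rand_seq(n: int, alphabet: str = BASES) -> str:
        return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))

    # free intergenic space: per chromosome, everything past the last gene
    free_cursor = {}
    for chrom, seq in genome.items():
        last = max((m.end for m in models if m.chrom == chrom), default=0)
        free_cursor[chrom] = last + 1000
    chrom_names = sorted(genome)

    def claim(chrom: str, length: int) -> tuple[int, int]:
        """Reserve [start, end) 0-based intergenic space on ``chrom``."""
        start = free_cursor[chrom]
        free_cursor[chrom] = start + length + 500
        if free_cursor[chrom] > len(genome[chrom]):
            raise SizingError(f"no intergenic room left on {chrom}")
        return start, start + length

    genes = sorted(models, key=lambda m: m.gene_id)
    if params.n_exact + params.n_fragment > len(genes):
        raise SizingError("not enough genes for the requested exact/fragment set")

    # exact annotated transcripts (+ duplicates and redundant locus-mates)
    for i in range(params.n_exact):
        m = genes[i]
        seq = extract_spliced(genome, m.chrom, m.exons, m.strand)
        segs = [(m.chrom, s - 1, e, m.strand) for s, e in m.exons]
        t = SimulatedTranscript(f"tx_exact{i:02d}", seq, f"locus_ex{i:02d}",
                                float(rng.integers(20, 100)), segs, "exact")
        out.append(t)
        if i < params.n_duplicate:
            out.append(SimulatedTranscript(
                f"tx_exact{i:02d}_dup", seq, f"locus_exdup{i:02d}",
                t.coverage / 2, segs, "duplicate"))
        if i < params.n_redundant:
            frac = seq[: max(150, len(seq) // 2)]
            out.append(SimulatedTranscript(
                f"tx_exact{i:02d}_red", frac, t.locus, t.coverage / 4,
                segs[:1], "non_representative"))

    # truncated fragments of other annotated transcripts: a slice of the CDS,
    # so they still match the known CDS set at full identity
    for i in range(params.n_fragment):
        m = genes[params.n_exact + i]
        cds = extract_spliced(genome, m.chrom, m.cds, m.strand)
        a = len(cds) // 6
        frag = cds[a:a + max(200, len(cds) // 2)]
        segs = [(m.chrom, m.cds[0][0] - 1, m.cds[0][0] - 1 + len(frag), m.strand)]
        out.append(SimulatedTranscript(
            f"tx_frag{i:02d}", frag, f"locus_fr{i:02d}",
            float(rng.integers(5, 40)), segs, "fragment"))

    # intergenic novels: UTR + ORF(120 codons incl. stop) + tail
    novel_full: list[SimulatedTranscript] = []
    for i in range(params.n_novel):
        chrom = chrom_names[i % len(chrom_names)]
        orf = _random_cds(rng, 120)
        seq = rand_seq(20, "CAG") + orf + rand_seq(200)
        n_ex = 1 + (i % 2)
        start, end = claim(chrom, len(seq) + (150 if n_ex == 2 else 0))
        if n_ex == 1:
            segs = [(chrom, start, start + len(seq), "+")]
        else:
            half = len(seq) // 2
            segs = [(chrom, start, start + half, "+"),
                    (chrom, start + half + 150, start + half + 150 + (len(seq) - half), "+")]
        t = SimulatedTranscript(f"tx_novel{i:02d}", seq, f"locus_nv{i:02d}",
                                float(rng.integers(10, 80)), segs, "novel")
        out.append(t)
        novel_full.append(t)

    # shorter isoforms of the first novels (same genomic locus, new assembler locus)
    for i in range(params.n_novel_isoform):
        full = novel_full[i]
        keep = 20 + 3 * 120  # UTR + complete ORF, tail dropped
        seq = full.sequence[:keep]
        c, s0, _, st = full.segments[0]
        segs = [(c, s0, s0 + keep, st)]
        out.append(SimulatedTranscript(
            f"tx_novel{i:02d}_iso", seq, f"locus_nviso{i:02d}",
            full.coverage, segs, "isoform_dropped"))

    # cross-chromosome chimeras
    for i in range(params.n_chimera):
        c1 = chrom_names[i % len(chrom_names)]
        c2 = chrom_names[(i + 1) % len(chrom_names)]
        seq = rand_seq(600)
        s1 = claim(c1, 300)
        s2 = claim(c2, 300)
        segs = [(c1, s1[0], s1[1], "+"), (c2, s2[0], s2[1], "+")]
        out.append(SimulatedTranscript(
            f"tx_chim{i:02d}", seq, f"locus_ch{i:02d}",
            float(rng.integers(5, 50)), segs, "chimera"))

    # over-span artifacts (> 10 kb genomic span on one chromosome)
    for i in range(params.n_long):
        chrom = chrom_names[-1 - i]
        orf = _random_cds(rng, 100)
        seq = rand_seq(20, "CAG") + orf + rand_seq(100)
        start, _ = claim(chrom, 12_000)
        half = len(seq) // 2
        segs = [(chrom, start, start + half, "+"),
                (chrom, start + 10_500, start + 10_500 + (len(seq) - half), "+")]
        out.append(SimulatedTranscript(
            f"tx_long{i:02d}", seq, f"locus_lg{i:02d}",
            float(rng.integers(5, 50)), segs, "over_span"))

    # ORF-less transcripts: no T forward => no ATG on either strand
    for i in range(params.n_orfless):
        chrom = chrom_names[i % len(chrom_names)]
        seq = rand_seq(400, "ACG")
        start, end = claim(chrom, len(seq))
        out.append(SimulatedTranscript(
            f"tx_noorf{i:02d}", seq, f"locus_no{i:02d}",
            float(rng.integers(5, 50)), [(chrom, start, end, "+")], "no_orf"))

    # unplaced: no genome segments at all
    for i in range(params.n_unplaced):
        out.append(SimulatedTranscript(
            f"tx_unpl{i:02d}", rand_seq(350), f"locus_un{i:02d}",
            float(rng.integers(5, 50)), [], "unplaced"))

    seg_df = pd.DataFrame(
        [r for t in out for r in _seg_rows(t)],
        columns=["chrom", "start", "end", "transcript_id", "score", "strand"],
    )
    truth = pd.DataFrame(
        [(t.transcript_id, t.intended_class) for t in out],
        columns=["transcript_id", "intended_class"],
    )
    return out, seg_df, truth


# --------------------------------------------------------------------------
# direct Ka/Ks ratio tables (for permutation-test studies)
# --------------------------------------------------------------------------

def simulate_kaks_table(n_chromosomes: int = 10, genes_per_chrom: int = 50,
                        median_ratio: float = 0.3, sigma: float = 0.5,
                        chrom_shift: dict[str, float] | None = None,
                        label_shift: dict[str, float] | None = None,
                        subgenome_props: tuple[float, float, float] = (0.6, 0.25, 0.15),
                        seed: int = 0) -> pd.DataFrame:
    """Per-gene Ka/Ks ratios drawn log-normally, with optional planted shifts.

    ``chrom_shift``/``label_shift`` multiply the ratios of a chromosome or
    sub-genome (e.g. ``{"chr01": 2.0}`` plants a +100% median shift). Used for
    calibration and power studies of the permutation tests without running the
    full sequence pipeline.
    """
    rng = np.random.default_rng([seed, _STREAM_KAKS])
    n = n_chromosomes * genes_per_chrom
    chroms = np.repeat([f"chr{i + 1:02d}" for i in range(n_chromosomes)], genes_per_chrom)
    labels = rng.choice(SUBGENOMES, size=n, p=list(subgenome_props))
    ratios = median_ratio * np.exp(rng.normal(0.0, sigma, size=n))
    for chrom, f in (chrom_shift or {}).items():
        ratios[chroms == chrom] *= f
    for lab, f in (label_shift or {}).items():
        ratios[labels == lab] *= f
    return pd.DataFrame({
        "gene_id": [f"g{i + 1:05d}" for i in range(n)],
        "chrom": chroms, "subgenome": labels, "ratio": ratios,
    })
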