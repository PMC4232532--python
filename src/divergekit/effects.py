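"""Structural and functional classification of SNPs against gene models.

A SNP is placed into one of {intergenic, intronic, CDS, five_prime_UTR,
three_prime_UTR} by interval membership (within a gene, CDS beats UTR beats
intron; any gene overlap beats intergenic). For CDS SNPs of complete models
the affected codon is extracted strand-aware from the spliced CDS and
translated with the standard code; a SNP is synonymous iff the reference and
alternate amino acids agree. Per-gene SNP rates are reported as SNPs per
100 bp of gene, with a centred 25-gene rolling mean that never crosses a
chromosome boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .errors import CoordinateError
from .models import GeneModel, point_in
from .seq import CODON_TABLE, extract_spliced

logger = logging.getLogger(__name__)

REGIONS = ("intergenic", "intronic", "CDS", "five_prime_UTR", "three_prime_UTR")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# most severe first, for the single-effect summary of SNPs in overlapping genes
_SEVERITY = {
    ("CDS", False): 0,   # nonsynonymous
    ("CDS", True): 1,    # synonymous
    ("CDS", None): 1,
    ("five_prime_UTR", None): 2,
    ("three_prime_UTR", None): 2,
    ("intronic", None): 3,
    ("intergenic", None): 4,
}


@dataclass(frozen=True)
class SnpEffect:
    """Classification of one SNP against one gene model (or intergenic)."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    region: str
    gene_id: str | None = None
    codon_position: int | None = None  # 1|2|3
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def synonymous(self) -> bool | None:
        if self.ref_aa is None:
            return None
        return self.ref_aa == self.alt_aa

    @property
    def severity(self) -> int:
        return _SEVERITY[(self.region, self.synonymous if self.region == "CDS" else None)]


class GeneIndex:
    """Interval index over gene spans for fast SNP-to-gene lookup."""

    def __init__(self, models: list[GeneModel]):
        self.models = models
        self._trees: dict[str, IntervalTree] = {}
        for i, m in enumerate(models):
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(m.start, m.end + 1, i)  # half-open internally

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.at(pos), key=lambda iv: iv.data)
        return [self.models[iv.data] for iv in hits]


def _classify_in_gene(chrom: str, pos: int, ref: str, alt: str,
                      model: GeneModel, genome: dict[str, str]) -> SnpEffect:
    base = SnpEffect(chrom, pos, ref, alt, "intronic", model.gene_id)
    if point_in(pos, model.cds):
        if model.incomplete:
            logger.info("SNP %s:%d in CDS of incomplete model %s; "
                        "codon fields omitted", chrom, pos, model.gene_id)
            return SnpEffect(chrom, pos, ref, alt, "CDS", model.gene_id)
        off = model.genomic_to_cds(pos)
        cds_seq = extract_spliced(genome, model.chrom, model.cds, model.strand)
        ci, cp = divmod(off, 3)
        ref_codon = cds_seq[3 * ci:3 * ci + 3]
        alt_cds_base = alt if model.strand == "+" else _COMPLEMENT[alt]
        alt_codon = ref_codon[:cp] + alt_cds_base + ref_codon[cp + 1:]
        return SnpEffect(
            chrom, pos, ref, alt, "CDS", model.gene_id,
            codon_position=cp + 1, ref_codon=ref_codon, alt_codon=alt_codon,
            ref_aa=CODON_TABLE[ref_codon], alt_aa=CODON_TABLE[alt_codon],
        )
    if point_in(pos, model.utr5):
        return SnpEffect(chrom, pos, ref, alt, "five_prime_UTR", model.gene_id)
    if point_in(pos, model.utr3):
        return SnpEffect(chrom, pos, ref, alt, "three_prime_UTR", model.gene_id)
    return base


def classify_snp_all(chrom: str, pos: int, ref: str, alt: str,
                     index: GeneIndex, genome: dict[str, str]) -> list[SnpEffect]:
    """One effect per overlapping gene; a single intergenic effect otherwise."""
    if chrom not in genome:
        raise CoordinateError(f"unknown chromosome {chrom!r}")
    if not 1 <= pos <= len(genome[chrom]):
        raise CoordinateError(f"{chrom}:{pos} outside chromosome")
    genes = index.overlapping(chrom, pos)
    if not genes:
        return [SnpEffect(chrom, pos, ref, alt, "intergenic")]
    return [_classify_in_gene(chrom, pos, ref, alt, m, genome) for m in genes]


def classify_snp(chrom: str, pos: int, ref: str, alt: str,
                 index: GeneIndex, genome: dict[str, str]) -> SnpEffect:
    """The single most severe effect of a SNP (CDS-nonsyn > CDS-syn > UTR >
    intron > intergenic)."""
    effects = classify_snp_all(chrom, pos, ref, alt, index, genome)
    return min(effects, key=lambda e: e.severity)


def codon_position_histogram(effects: list[SnpEffect]) -> dict[int, int]:
    """Counts of CDS SNPs at codon positions 1, 2, 3."""
    hist = {1: 0, 2: 0, 3: 0}
    for e in effects:
        if e.region == "CDS" and e.codon_position is not None:
            hist[e.codon_position] += 1
    return hist


@dataclass(frozen=True)
class GeneSnpRate:
    gene_id: str
    chrom: str
    start: int
    snp_count: int
    gene_length: int
    rate: float  # SNPs per 100 bp of gene


def gene_snp_rate(snps: pd.DataFrame, models: list[GeneModel],
                  length: str = "span") -> pd.DataFrame:
    """Per-gene SNP rate, 100 * count / gene length.

    ``snps`` needs chrom and pos columns. ``length`` is the genomic span
    (start..end) by default, or "exonic" for summed exon length. Genes are
    returned ordered by chromosome then start.
    """
    index = GeneIndex(models)
    counts: dict[str, int] = {m.gene_id: 0 for m in models}
    for row in snps.itertuples(index=False):
        for m in index.overlapping(row.chrom, int(row.pos)):
            counts[m.gene_id] += 1
    rows = []
    for m in sorted(models, key=lambda m: (m.chrom, m.start)):
        glen = m.span if length == "span" else sum(e - s + 1 for s, e in m.exons)
        if glen == 0:
            raise ValueError(f"zero-length gene {m.gene_id}")
        rows.append((m.gene_id, m.chrom, m.start, counts[m.gene_id], glen,
                     100.0 * counts[m.gene_id] / glen))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "snp_count",
                                       "gene_length", "rate"])


def rolling_mean(rates: pd.DataFrame, window: int = 25,
                 value_col: str = "rate") -> pd.Series:
    """Centred rolling mean over genes, shrinking at chromosome edges.

    Windows never mix genes from different chromosomes; genes must already be
    ordered by chromosome then start (as :func:`gene_snp_rate` returns them).
    """
    return (rates.groupby("chrom", sort=False)[value_col]
            .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean()))


def effects_to_dataframe(effects: list[SnpEffect]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "chrom": e.chrom, "pos": e.pos, "ref": e.ref_base, "alt": e.alt_base,
        "region": e.region, "gene_id": e.gene_id,
        "codon_position": e.codon_position, "ref_codon": e.ref_codon,
        "alt_codon": e.alt_codon, "ref_aa": e.ref_aa, "alt_aa": e.alt_aa,
        "synonymous": e.synonymous,
    } for e in effects])
    return df


def region_summary(effects: list[SnpEffect]) -> pd.DataFrame:
    """Region counts, reporting UTR+CDS both separately and as 'exonic'."""
    df = effects_to_dataframe(effects)
    counts = df["region"].value_counts().to_dict()
    exonic = sum(counts.get(r, 0) for r in ("CDS", "five_prime_UTR", "three_prime_UTR"))
    rows = [(r, counts.get(r, 0)) for r in REGIONS] + [("exonic", exonic)]
    return pd.DataFrame(rows, columns=["region", "count"])
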