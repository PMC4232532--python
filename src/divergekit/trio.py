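"""Trio deduction of between-genotype SNPs and noise-reduction genotyping.

Two inbred genotypes are each called against the same reference; a
genotype1-vs-genotype2 SNP is deduced at any position where the two call
sets imply different alleles. A variant in one genotype combines with the
other genotype's evidence in one of five ways:

(a) g1 variant, g2 uncalled but covered and modal base = reference -> SNP
    (alt1 vs ref);
(b) the mirror case for g2;
(c) both called with different alternates -> SNP (alt1 vs alt2);
(d) both called with the same alternate -> shared divergence from the
    reference, not a between-genotype SNP (excluded_shared);
(e) counterpart coverage below ``min_depth`` -> excluded_coverage.

A counterpart that is uncalled yet does not match the reference (a mixed
pileup) is recorded as filtered_noise: its alignment gives an ambiguous
signal, the same failure mode the noise filter targets.

The noise-reduction step re-interrogates both genotypes' allele counts at
every putative SNP: a site is kept only when, in each genotype, the majority
of reads match that genotype's expected allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .calling import CallingThresholds, VariantCall
from .errors import DivergekitError
from .io import VcfRecord, write_vcf
from .seq import BASES

logger = logging.getLogger(__name__)

STATUSES = ("putative", "kept", "filtered_noise", "excluded_coverage",
            "excluded_shared")


@dataclass(frozen=True)
class TrioSNP:
    """A putative between-genotype polymorphism with per-genotype evidence."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    allele_g1: str
    allele_g2: str
    depth_g1: int
    depth_g2: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status in ("putative", "kept") and self.allele_g1 == self.allele_g2:
            raise ValueError("between-genotype SNP with identical alleles")


@dataclass(frozen=True)
class GenotypeScore:
    """Read support for one genotype's expected allele at one position."""

    chrom: str
    pos: int
    sample: str
    reads_matching_expected: int
    reads_matching_other: int
    flagged: bool = False  # no count record at this position

    @property
    def depth(self) -> int:
        return self.reads_matching_expected + self.reads_matching_other

    @property
    def match_fraction(self) -> float:
        if self.depth == 0:
            return 0.0
        return self.reads_matching_expected / self.depth


def _counts_index(counts: pd.DataFrame) -> dict[tuple[str, int], dict[str, int]]:
    idx = {}
    for row in counts.itertuples(index=False):
        idx[(row.chrom, int(row.pos))] = {b: int(getattr(row, b)) for b in BASES}
    return idx


def _modal_base(base_counts: dict[str, int]) -> str:
    return max(base_counts, key=base_counts.get)  # alphabetical tie-break


def deduce_between_genotype_snps(calls_g1: list[VariantCall],
                                 calls_g2: list[VariantCall],
                                 counts_g1: pd.DataFrame,
                                 counts_g2: pd.DataFrame,
                                 thresholds: CallingThresholds | None = None
                                 ) -> list[TrioSNP]:
    """Deduce genotype1-vs-genotype2 SNPs from two vs-reference call sets.

    Returns every candidate position with its status; callers typically keep
    the ``putative`` subset for scoring. Raises on conflicting reference
    bases between the two call sets.
    """
    th = thresholds or CallingThresholds()
    c1 = {(c.chrom, c.pos): c for c in calls_g1}
    c2 = {(c.chrom, c.pos): c for c in calls_g2}
    idx1 = _counts_index(counts_g1)
    idx2 = _counts_index(counts_g2)

    out: list[TrioSNP] = []
    for key in sorted(set(c1) | set(c2)):
        chrom, pos = key
        v1, v2 = c1.get(key), c2.get(key)
        ref = (v1 or v2).ref_base
        if v1 and v2 and v1.ref_base != v2.ref_base:
            raise DivergekitError(
                f"conflicting reference bases at {chrom}:{pos}: "
                f"{v1.ref_base} vs {v2.ref_base}"
            )

        if v1 and v2:
            status = "excluded_shared" if v1.alt_base == v2.alt_base else "putative"
            out.append(TrioSNP(chrom, pos, ref, v1.alt_base, v2.alt_base,
                               v1.depth, v2.depth, status))
            continue

        # one-sided variant: interrogate the counterpart's counts
        variant, other_idx = (v1, idx2) if v1 else (v2, idx1)
        counter = other_idx.get(key)
        counter_depth = sum(counter.values()) if counter else 0
        if counter is None or counter_depth < th.min_depth:
            status, counter_allele = "excluded_coverage", ref
        elif _modal_base(counter) == ref:
            status, counter_allele = "putative", ref
        else:
            status, counter_allele = "filtered_noise", _modal_base(counter)
            logger.debug("counterpart at %s:%d uncalled but modal base %r != ref",
                         chrom, pos, counter_allele)
        if v1:
            a1, a2, d1, d2 = variant.alt_base, counter_allele, variant.depth, counter_depth
        else:
            a1, a2, d1, d2 = counter_allele, variant.alt_base, counter_depth, variant.depth
        out.append(TrioSNP(chrom, pos, ref, a1, a2, d1, d2, status))
    return out


def score_genotypes(trio_snps: list[TrioSNP], counts_g1: pd.DataFrame,
                    counts_g2: pd.DataFrame,
                    samples: tuple[str, str] = ("G1", "G2")
                    ) -> list[tuple[GenotypeScore, GenotypeScore]]:
    """Count reads matching each genotype's expected allele at each SNP.

    SNPs must be ``putative``. A missing count record scores as depth 0 and
    is flagged.
    """
    idx1 = _counts_index(counts_g1)
    idx2 = _counts_index(counts_g2)
    pairs = []
    for snp in trio_snps:
        if snp.status != "putative":
            raise ValueError(f"score_genotypes expects putative SNPs, "
                             f"got {snp.status} at {snp.chrom}:{snp.pos}")
        scores = []
        for sample, expected, idx in ((samples[0], snp.allele_g1, idx1),
                                      (samples[1], snp.allele_g2, idx2)):
            rec = idx.get((snp.chrom, snp.pos))
            if rec is None:
                scores.append(GenotypeScore(snp.chrom, snp.pos, sample, 0, 0,
                                            flagged=True))
                continue
            match = rec.get(expected, 0)
            other = sum(rec.values()) - match
            scores.append(GenotypeScore(snp.chrom, snp.pos, sample, match, other))
        pairs.append((scores[0], scores[1]))
    return pairs


def noise_filter(trio_snps: list[TrioSNP],
                 scores: list[tuple[GenotypeScore, GenotypeScore]],
                 majority_threshold: float = 0.8) -> list[TrioSNP]:
    """Keep a putative SNP iff both genotypes show a clear read majority for
    their expected allele.

    ``majority_threshold`` is exclusive: kept iff match_fraction >
    majority_threshold on BOTH sides; everything else becomes
    ``filtered_noise``. The default of 0.8 (a 4:1 read majority) sits midway
    between the two regimes the filter must separate -- a fixed allele read
    at ~99% and a residually segregating 50/50 mixture -- so that binomial
    sampling at typical depths essentially never crosses it from either
    side; a bare >0.5 majority lets half of all 50/50 sites through.
    """
    if len(trio_snps) != len(scores):
        raise ValueError("one score pair required per putative SNP")
    out = []
    for snp, (s1, s2) in zip(trio_snps, scores):
        ok = (s1.match_fraction > majority_threshold
              and s2.match_fraction > majority_threshold)
        out.append(replace(snp, status="kept" if ok else "filtered_noise"))
    return out


def trio_pipeline(counts_g1: pd.DataFrame, counts_g2: pd.DataFrame,
                  reference: dict[str, str],
                  thresholds: CallingThresholds | None = None,
                  majority_threshold: float = 0.8,
                  samples: tuple[str, str] = ("G1", "G2")
                  ) -> tuple[list[TrioSNP], pd.DataFrame]:
    """call -> deduce -> score -> noise-filter, returning (kept, audit table).

    The audit table lists every candidate position with its final status.
    """
    from .calling import call_variants

    th = thresholds or CallingThresholds()
    calls1 = call_variants(counts_g1, reference, th)
    calls2 = call_variants(counts_g2, reference, th)
    candidates = deduce_between_genotype_snps(calls1, calls2, counts_g1,
                                              counts_g2, th)
    putative = [s for s in candidates if s.status == "putative"]
    pairs = score_genotypes(putative, counts_g1, counts_g2, samples)
    resolved = noise_filter(putative, pairs, majority_threshold)
    final = [s for s in candidates if s.status != "putative"] + resolved
    final.sort(key=lambda s: (s.chrom, s.pos))
    audit = pd.DataFrame(
        [(s.chrom, s.pos, s.ref_base, s.allele_g1, s.allele_g2,
          s.depth_g1, s.depth_g2, s.status) for s in final],
        columns=["chrom", "pos", "ref_base", "allele_g1", "allele_g2",
                 "depth_g1", "depth_g2", "status"],
    )
    kept = [s for s in final if s.status == "kept"]
    return kept, audit


def export_trio_vcf(snps: list[TrioSNP], path: str,
                    samples: tuple[str, str] = ("G1", "G2"),
                    contigs: dict[str, int] | None = None) -> None:
    """Write trio SNPs (typically the kept set) as a two-sample VCF."""
    records = []
    for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        alts = tuple(sorted({a for a in (s.allele_g1, s.allele_g2)
                             if a != s.ref_base}))
        records.append(VcfRecord(
            s.chrom, s.pos, s.ref_base, alts,
            genotypes={samples[0]: s.allele_g1, samples[1]: s.allele_g2},
            depths={samples[0]: s.depth_g1, samples[1]: s.depth_g2},
        ))
    write_vcf(records, list(samples), path, contigs=contigs)
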