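"""Per-genotype variant calling from allele-count tables.

Each genotype is called against the reference independently: a site yields a
call iff its depth reaches ``min_depth`` and the modal non-reference base
accounts for at least ``min_alt_fraction`` of the reads. The genotypes are
inbred, so only the single modal alternate allele is considered; minor
alternates and ties are logged. Positions whose reference base is ambiguous
(N) are skipped with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import CoordinateError
from .io import VcfRecord, write_vcf
from .seq import BASES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallingThresholds:
    """Minimum evidence for a per-genotype variant call.

    ``min_depth`` follows the four-read coverage floor used throughout the
    pipeline. ``min_alt_fraction`` is the allele-purity cutoff for calling an
    inbred (effectively homozygous) genotype. The default of 0.75 makes the
    per-site miss probability negligible under a 1% per-base miscall rate at
    any depth (an error load above a quarter of the reads is essentially
    impossible), while a 50/50 heterogeneous site still almost never reaches
    it -- and when one does, the trio comparison discards it as a shared
    allele. Tighter cutoffs (0.9) reject measurable numbers of genuine
    homozygous sites at depths in the twenties, where the binomial error
    load regularly exceeds 10% of reads less one.
    """

    min_depth: int = 4
    min_alt_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must be in (0, 1]")


@dataclass(frozen=True)
class VariantCall:
    """A single-genotype substitution call against the reference."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    depth: int
    alt_fraction: float
    sample: str


def call_variants(counts: pd.DataFrame, reference: dict[str, str],
                  thresholds: CallingThresholds | None = None) -> list[VariantCall]:
    """Call variants from an allele-count table against a reference.

    ``counts`` has columns chrom, pos (1-based), sample, A, C, G, T. A call
    is emitted iff depth >= min_depth and the modal non-reference base has
    fraction >= min_alt_fraction; at most one call per position per sample.
    Ties for the modal alternate are broken alphabetically (and logged).
    """
    th = thresholds or CallingThresholds()
    calls: list[VariantCall] = []
    for row in counts.itertuples(index=False):
        chrom, pos = row.chrom, int(row.pos)
        if chrom not in reference:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        seq = reference[chrom]
        if not 1 <= pos <= len(seq):
            raise CoordinateError(
                f"{chrom}:{pos} beyond chromosome end ({len(seq)})"
            )
        ref = seq[pos - 1]
        if ref not in BASES:
            logger.info("skipping %s:%d: ambiguous reference base %r", chrom, pos, ref)
            continue
        base_counts = {b: int(getattr(row, b)) for b in BASES}
        depth = sum(base_counts.values())
        if depth < th.min_depth:
            continue
        alt_counts = {b: c for b, c in base_counts.items() if b != ref}
        # max() on the alphabetically ordered dict breaks ties alphabetically
        alt = max(alt_counts, key=alt_counts.get)
        if list(alt_counts.values()).count(alt_counts[alt]) > 1 and alt_counts[alt] > 0:
            logger.debug("tie for modal alternate at %s:%d", chrom, pos)
        if alt_counts[alt] == 0:
            continue
        others = [b for b, c in alt_counts.items() if b != alt and c > 0]
        if others:
            logger.debug("minor alternate alleles at %s:%d ignored: %s",
                         chrom, pos, others)
        fraction = alt_counts[alt] / depth
        if fraction >= th.min_alt_fraction:
            calls.append(VariantCall(chrom, pos, ref, alt, depth, fraction,
                                     str(row.sample)))
    return calls


def calls_to_dataframe(calls: list[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls],
                        columns=["chrom", "pos", "ref_base", "alt_base",
                                 "depth", "alt_fraction", "sample"])


def export_vcf(calls: list[VariantCall], path: str,
               contigs: dict[str, int] | None = None) -> None:
    """Write per-genotype calls as a VCF 4.2 file (one record per site)."""
    samples = sorted({c.sample for c in calls}) or ["sample"]
    by_site: dict[tuple[str, int], list[VariantCall]] = {}
    for c in calls:
        by_site.setdefault((c.chrom, c.pos), []).append(c)
    records = []
    for (chrom, pos), site_calls in sorted(by_site.items()):
        ref = site_calls[0].ref_base
        alts = tuple(sorted({c.alt_base for c in site_calls}))
        records.append(VcfRecord(
            chrom, pos, ref, alts,
            genotypes={c.sample: c.alt_base for c in site_calls},
            depths={c.sample: c.depth for c in site_calls},
        ))
    write_vcf(records, samples, path, contigs=contigs)
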