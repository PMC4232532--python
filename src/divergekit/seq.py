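"""Small sequence utilities shared across modules.

Translation and reverse complement delegate to Biopython; codon bookkeeping
(the standard nuclear code only — no indels, no alternative codes) is exposed
as plain dict/set lookups because the simulator and the NG86 estimator both
need per-codon queries in tight loops.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

BASES = "ACGT"

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
for _stop in STOP_CODONS:
    CODON_TABLE[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
)

_PURINES = {"A", "G"}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) with the standard code."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return str(Seq(cds).translate())


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T substitution."""
    return a != b and (a in _PURINES) == (b in _PURINES)


def extract_spliced(genome: dict[str, str], chrom: str,
                    intervals: list[tuple[int, int]], strand: str) -> str:
    """Strand-aware spliced concatenation of 1-based inclusive intervals.

    Intervals are given in genomic order; on the minus strand the
    concatenation is reverse-complemented so the result reads 5'->3'.
    """
    seq = genome[chrom]
    for s, e in intervals:
        if s < 1 or e > len(seq):
            raise IndexError(
                f"interval ({s},{e}) outside {chrom} (length {len(seq)})"
            )
    joined = "".join(seq[s - 1:e] for s, e in sorted(intervals))
    return revcomp(joined) if strand == "-" else joined
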