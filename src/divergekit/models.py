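"""Shared domain types: gene models and interval arithmetic.

Coordinates are GFF3-style throughout the package: 1-based, inclusive on both
ends. Conversions to/from BED (0-based, half-open) live in :mod:`divergekit.io`
so that off-by-one logic exists in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Interval = tuple[int, int]  # 1-based inclusive


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


def intervals_len(ivs: list[Interval]) -> int:
    return sum(interval_len(iv) for iv in ivs)


def point_in(pos: int, ivs: list[Interval]) -> bool:
    return any(s <= pos <= e for s, e in ivs)


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """a \\ b for sorted, non-overlapping 1-based inclusive interval lists."""
    out: list[Interval] = []
    for s, e in a:
        pieces = [(s, e)]
        for bs, be in b:
            nxt: list[Interval] = []
            for ps, pe in pieces:
                if be < ps or bs > pe:
                    nxt.append((ps, pe))
                    continue
                if ps < bs:
                    nxt.append((ps, bs - 1))
                if pe > be:
                    nxt.append((be + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


@dataclass
class GeneModel:
    """A protein-coding gene model with explicit strand and sorted intervals.

    ``exons`` and ``cds`` are sorted, non-overlapping 1-based inclusive
    intervals on ``chrom``. 5'/3' UTRs are derived from exon-minus-CDS
    geometry. A model whose total CDS length is not divisible by 3 is flagged
    ``incomplete`` and excluded from codon-level logic by callers.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval]
    subgenome: str | None = None  # LF / MF1 / MF2
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for ivs in (self.exons, self.cds):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping intervals in {self.gene_id}")

    # --- derived geometry -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def cds_len(self) -> int:
        return intervals_len(self.cds)

    @property
    def incomplete(self) -> bool:
        return not self.cds or self.cds_len % 3 != 0

    @property
    def utrs(self) -> list[Interval]:
        return subtract_intervals(self.exons, self.cds)

    @property
    def utr5(self) -> list[Interval]:
        if not self.cds:
            return []
        cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
        if self.strand == "+":
            return [iv for iv in self.utrs if iv[1] < cds_start]
        return [iv for iv in self.utrs if iv[0] > cds_end]

    @property
    def utr3(self) -> list[Interval]:
        if not self.cds:
            return []
        cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
        if self.strand == "+":
            return [iv for iv in self.utrs if iv[0] > cds_end]
        return [iv for iv in self.utrs if iv[1] < cds_start]

    def introns(self) -> list[Interval]:
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    # --- CDS coordinate mapping -------------------------------------------

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to a 0-based offset in the spliced CDS.

        Strand-aware: offset 0 is the first base of the start codon. Returns
        None when ``pos`` is not inside any CDS interval.
        """
        if not point_in(pos, self.cds):
            return None
        if self.strand == "+":
            off = 0
            for s, e in self.cds:
                if pos > e:
                    off += e - s + 1
                else:
                    return off + (pos - s)
        else:
            off = 0
            for s, e in reversed(self.cds):
                if pos < s:
                    off += e - s + 1
                else:
                    return off + (e - pos)
        return None  # pragma: no cover
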