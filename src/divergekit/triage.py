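"""Multi-stage triage of redundant assembled transcripts.

Assembled transcript sets are reduced to a clean novel set by a fixed
cascade: exact-duplicate removal, per-locus representative selection,
removal of transcripts matching known CDS (>= 95% identity over >= 100
aligned bases, k-mer-seeded), exon-chain construction from genome alignment
segments, chimera removal (substantial segments on two chromosomes),
removal of transcripts spanning more than 10 kb of genome, removal of
transcripts without an ORF of at least 50 aa, and best-isoform selection by
maximum length. Transcripts are also classified against a reference
annotation with gffcompare-style class codes (=, c, j, o, x, i, u).

Every input transcript ends in exactly one terminal disposition; transcripts
with no genome segments are set aside in an "unplaced" bin rather than
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .models import GeneModel
from .seq import revcomp

logger = logging.getLogger(__name__)

CLASS_CODES = ("=", "c", "j", "o", "x", "i", "u")


@dataclass(frozen=True)
class AssembledTranscript:
    """One assembled transcript with its assembler locus and coverage."""

    transcript_id: str
    sequence: str
    locus: str
    coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MappedTranscript:
    """A transcript's genome alignment reduced to a merged exon chain."""

    transcript_id: str
    segments: list[tuple[str, int, int, str]]  # (chrom, start, end, strand), BED
    exon_chain: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def chroms(self) -> list[str]:
        return sorted({c for c, _, _ in self.exon_chain})

    @property
    def strand(self) -> str:
        strands = {s for _, _, _, s in self.segments}
        return strands.pop() if len(strands) == 1 else "."

    def genomic_span(self) -> int:
        """max end - min start, maximised over chromosomes."""
        best = 0
        for chrom in self.chroms:
            ivs = [(s, e) for c, s, e in self.exon_chain if c == chrom]
            best = max(best, max(e for _, e in ivs) - min(s for s, _ in ivs))
        return best

    def introns(self, chrom: str | None = None) -> list[tuple[str, int, int]]:
        out = []
        for c in self.chroms:
            ivs = sorted((s, e) for cc, s, e in self.exon_chain if cc == c)
            if chrom is not None and c != chrom:
                continue
            out += [(c, e1, s2) for (_, e1), (s2, _) in zip(ivs, ivs[1:])]
        return out


@dataclass(frozen=True)
class OrfRecord:
    """A complete start-to-stop ORF on one strand of a transcript.

    ``start``/``end`` are 0-based half-open on the scanned sequence (the
    reverse complement for strand '-'); the interval includes the stop
    codon, so end - start = 3 * (protein_length + 1).
    """

    transcript_id: str
    strand: str
    frame: int  # 0..2 on the scanned strand
    start: int
    end: int
    protein_length: int


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def remove_exact_duplicates(transcripts: list) -> tuple[list, list]:
    """Drop byte-identical sequences, keeping the lexicographically first id."""
    by_seq: dict[str, list] = {}
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        by_seq.setdefault(t.sequence, []).append(t)
    kept, dropped = [], []
    for group in by_seq.values():
        kept.append(group[0])
        dropped += group[1:]
    kept.sort(key=lambda t: t.transcript_id)
    return kept, dropped


def select_representative(transcripts: list) -> tuple[list, list]:
    """One transcript per assembler locus: max (coverage, length, then id)."""
    groups: dict[str, list] = {}
    for t in transcripts:
        groups.setdefault(t.locus, []).append(t)
    kept, dropped = [], []
    for group in groups.values():
        group.sort(key=lambda t: (-t.coverage, -len(t.sequence), t.transcript_id))
        kept.append(group[0])
        dropped += group[1:]
    kept.sort(key=lambda t: t.transcript_id)
    return kept, dropped


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def match_known(transcripts: list, reference_cds: dict[str, str],
                min_identity: float = 0.95, min_aligned: int = 100,
                seed_k: int = 15) -> tuple[list, list]:
    """Partition transcripts into (known, candidate_novel) against known CDS.

    A transcript is known iff it aligns to some reference CDS at
    >= min_identity over >= min_aligned bases. Candidate pairs are seeded by
    shared ``seed_k``-mers (both orientations) and verified with an edlib
    infix alignment of the shorter sequence within the longer; identity is
    1 - edit_distance / aligned_query_length.
    """
    index: dict[str, set[str]] = {}
    for cid, cseq in reference_cds.items():
        for kmer in _kmers(cseq, seed_k):
            index.setdefault(kmer, set()).add(cid)

    def hits(seq: str) -> set[str]:
        found: set[str] = set()
        for i in range(0, len(seq) - seed_k + 1):
            found |= index.get(seq[i:i + seed_k], set())
        return found

    known, novel = [], []
    for t in transcripts:
        is_known = False
        for oriented in (t.sequence, revcomp(t.sequence)):
            for cid in sorted(hits(oriented)):
                cseq = reference_cds[cid]
                query, target = ((oriented, cseq) if len(oriented) <= len(cseq)
                                 else (cseq, oriented))
                if len(query) < min_aligned:
                    continue
                dist = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
                if 1.0 - dist / len(query) >= min_identity:
                    is_known = True
                    break
            if is_known:
                break
        (known if is_known else novel).append(t)
    return known, novel


def merge_segments(segments: list[tuple[str, int, int, str]]
                   ) -> list[tuple[str, int, int]]:
    """Union of overlapping/adjacent same-chromosome segments (BED half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, _ in segments:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlapping or adjacent
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def build_transcript_model(transcript_id: str,
                           segments: list[tuple[str, int, int, str]]
                           ) -> MappedTranscript:
    """Join a transcript's alignment segments into a sorted merged exon chain."""
    if not segments:
        raise ValueError(f"{transcript_id}: no alignment segments")
    return MappedTranscript(transcript_id, sorted(segments),
                            exon_chain=merge_segments(segments))


def is_chimera(mapped: MappedTranscript, min_segment: int = 50) -> bool:
    """Chimeric iff substantial exons (>= min_segment bp) lie on >= 2 chromosomes."""
    chroms = {c for c, s, e in mapped.exon_chain if e - s >= min_segment}
    return len(chroms) >= 2


def detect_chimeras(mapped: list[MappedTranscript],
                    min_segment: int = 50) -> set[str]:
    return {m.transcript_id for m in mapped if is_chimera(m, min_segment)}


def span_filter(mapped: list[MappedTranscript],
                max_span: int = 10_000) -> tuple[list[MappedTranscript], list[MappedTranscript]]:
    """Retain transcripts whose genomic span is at most ``max_span`` bp."""
    kept = [m for m in mapped if m.genomic_span() <= max_span]
    dropped = [m for m in mapped if m.genomic_span() > max_span]
    return kept, dropped


def find_orfs(transcript_id: str, sequence: str,
              min_protein_length: int = 50
              ) -> tuple[list[OrfRecord], OrfRecord | None]:
    """All complete start-to-stop ORFs on both strands, three frames each.

    For each stop codon in each frame the ORF starts at the first upstream
    ATG. The primary ORF is the longest (ties: '+' strand first, then
    smallest start).
    """
    orfs: list[OrfRecord] = []
    for strand, seq in (("+", sequence.upper()), ("-", revcomp(sequence.upper()))):
        for frame in range(3):
            start_at: int | None = None
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i:i + 3]
                if start_at is None and codon == "ATG":
                    start_at = i
                elif codon in ("TAA", "TAG", "TGA") and start_at is not None:
                    plen = (i - start_at) // 3
                    if plen >= min_protein_length:
                        orfs.append(OrfRecord(transcript_id, strand, frame,
                                              start_at, i + 3, plen))
                    start_at = None
    primary = None
    if orfs:
        primary = min(orfs, key=lambda o: (-o.protein_length,
                                           0 if o.strand == "+" else 1, o.start))
    return sorted(orfs, key=lambda o: (o.strand, o.frame, o.start)), primary


def best_isoform(mapped: list[MappedTranscript],
                 lengths: dict[str, int]) -> tuple[list[MappedTranscript], list[MappedTranscript]]:
    """One transcript per genomic locus, by maximum transcript length.

    Loci are connected components of exon-chain overlap on the same
    chromosome. Ties break to the lexicographically smallest id (logged).
    """
    events: dict[str, list[tuple[int, int, int]]] = {}
    for i, m in enumerate(mapped):
        for chrom, s, e in m.exon_chain:
            events.setdefault(chrom, []).append((s, e, i))
    parent = list(range(len(mapped)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for chrom, ivs in events.items():
        ivs.sort()
        cur_end, cur_root = -1, -1
        for s, e, i in ivs:
            if s < cur_end:
                parent[find(i)] = find(cur_root)
                cur_end = max(cur_end, e)
            else:
                cur_end, cur_root = e, i
    groups: dict[int, list[MappedTranscript]] = {}
    for i, m in enumerate(mapped):
        groups.setdefault(find(i), []).append(m)
    kept, dropped = [], []
    for group in groups.values():
        group.sort(key=lambda m: (-lengths[m.transcript_id], m.transcript_id))
        if len(group) > 1 and lengths[group[0].transcript_id] == lengths[group[1].transcript_id]:
            logger.debug("isoform length tie at %s", group[0].transcript_id)
        kept.append(group[0])
        dropped += group[1:]
    kept.sort(key=lambda m: m.transcript_id)
    return kept, dropped


# --------------------------------------------------------------------------
# class codes
# --------------------------------------------------------------------------

def _ref_chain(model: GeneModel) -> list[tuple[int, int]]:
    """Reference exon chain in BED coordinates (0-based half-open)."""
    return [(s - 1, e) for s, e in model.exons]


def _classify_vs_ref(t: MappedTranscript, ref: GeneModel) -> str | None:
    """Class of ``t`` against a single reference model, or None if unrelated."""
    chain = [(s, e) for c, s, e in t.exon_chain if c == ref.chrom]
    if not chain:
        return None
    ref_chain = _ref_chain(ref)
    t_span = (chain[0][0], chain[-1][1])
    r_span = (ref_chain[0][0], ref_chain[-1][1])
    if t_span[1] <= r_span[0] or t_span[0] >= r_span[1]:
        return None
    t_introns = [(e1, s2) for (_, e1), (s2, _) in zip(chain, chain[1:])]
    r_introns = [(e1, s2) for (_, e1), (s2, _) in zip(ref_chain, ref_chain[1:])]
    same_strand = t.strand == ref.strand or t.strand == "."
    exonic_overlap = any(
        s < re and e > rs for s, e in chain for rs, re in ref_chain
    )
    if same_strand:
        if t_introns == r_introns and (t_introns or exonic_overlap):
            return "="
        contained = all(
            any(rs <= s and e <= re for rs, re in ref_chain) for s, e in chain
        )
        if contained and all(iv in r_introns for iv in t_introns):
            return "c"
        if any(iv in r_introns for iv in t_introns):
            return "j"
        if exonic_overlap:
            return "o"
    elif exonic_overlap:
        return "x"
    if not exonic_overlap:
        for rs, re in [(e1, s2) for (_, e1), (s2, _) in zip(ref_chain, ref_chain[1:])]:
            if rs <= t_span[0] and t_span[1] <= re:
                return "i"
    return None


def classify_transcripts(mapped: list[MappedTranscript],
                         reference: list[GeneModel]) -> dict[str, str]:
    """gffcompare-style class code per transcript, precedence = c j o x i u."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in reference:
        by_chrom.setdefault(m.chrom, []).append(m)
    rank = {code: i for i, code in enumerate(CLASS_CODES)}
    out = {}
    for t in mapped:
        codes = []
        for chrom in t.chroms:
            for ref in by_chrom.get(chrom, []):
                code = _classify_vs_ref(t, ref)
                if code is not None:
                    codes.append(code)
        out[t.transcript_id] = min(codes, key=rank.get) if codes else "u"
    return out


# --------------------------------------------------------------------------
# the cascade
# --------------------------------------------------------------------------

@dataclass
class TriageResult:
    novel: list  # surviving transcripts
    dispositions: dict[str, str]  # transcript_id -> terminal disposition
    stage_counts: pd.DataFrame  # survivors after each stage
    class_codes: dict[str, str]  # for transcripts reaching classification


DISPOSITIONS = ("duplicate", "non_representative", "known", "unplaced",
                "chimera", "over_span", "no_orf", "isoform_dropped", "novel")


def triage_pipeline(transcripts: list, segments: pd.DataFrame,
                    reference_cds: dict[str, str],
                    reference_models: list[GeneModel] | None = None,
                    min_identity: float = 0.95, max_span: int = 10_000,
                    min_protein_length: int = 50) -> TriageResult:
    """Run the full filter cascade and account for every input transcript.

    ``segments`` is a BED6 DataFrame (chrom, start, end, transcript_id,
    score, strand; 0-based half-open). Returns the novel survivors plus a
    per-stage survivor-count table and a terminal disposition for each input.
    """
    seg_by_tx: dict[str, list[tuple[str, int, int, str]]] = {}
    for row in segments.itertuples(index=False):
        seg_by_tx.setdefault(row.transcript_id, []).append(
            (row.chrom, int(row.start), int(row.end), row.strand)
        )
    dispositions: dict[str, str] = {}
    counts = [("input", len(transcripts))]

    current, dropped = remove_exact_duplicates(transcripts)
    dispositions.update({t.transcript_id: "duplicate" for t in dropped})
    counts.append(("deduplicated", len(current)))

    current, dropped = select_representative(current)
    dispositions.update({t.transcript_id: "non_representative" for t in dropped})
    counts.append(("representative", len(current)))

    known, current = match_known(current, reference_cds, min_identity=min_identity)
    dispositions.update({t.transcript_id: "known" for t in known})
    counts.append(("candidate_novel", len(current)))

    placed, unplaced = [], []
    for t in current:
        (placed if seg_by_tx.get(t.transcript_id) else unplaced).append(t)
    dispositions.update({t.transcript_id: "unplaced" for t in unplaced})
    if unplaced:
        logger.info("%d transcripts have no genome segments (unplaced bin)",
                    len(unplaced))
    mapped = [build_transcript_model(t.transcript_id, seg_by_tx[t.transcript_id])
              for t in placed]
    counts.append(("mapped", len(mapped)))

    chimeric = detect_chimeras(mapped)
    dispositions.update({tid: "chimera" for tid in chimeric})
    mapped = [m for m in mapped if m.transcript_id not in chimeric]
    counts.append(("non_chimeric", len(mapped)))

    mapped, over = span_filter(mapped, max_span=max_span)
    dispositions.update({m.transcript_id: "over_span" for m in over})
    counts.append(("within_span", len(mapped)))

    seq_by_tx = {t.transcript_id: t.sequence for t in transcripts}
    with_orf = []
    for m in mapped:
        orfs, _ = find_orfs(m.transcript_id, seq_by_tx[m.transcript_id],
                            min_protein_length)
        if orfs:
            with_orf.append(m)
        else:
            dispositions[m.transcript_id] = "no_orf"
    counts.append(("orf_bearing", len(with_orf)))

    lengths = {tid: len(seq) for tid, seq in seq_by_tx.items()}
    final_mapped, iso_dropped = best_isoform(with_orf, lengths)
    dispositions.update({m.transcript_id: "isoform_dropped" for m in iso_dropped})
    dispositions.update({m.transcript_id: "novel" for m in final_mapped})
    counts.append(("novel", len(final_mapped)))

    class_codes = classify_transcripts(final_mapped, reference_models or [])
    novel_ids = {m.transcript_id for m in final_mapped}
    novel = [t for t in transcripts if t.transcript_id in novel_ids]
    return TriageResult(
        novel=novel, dispositions=dispositions,
        stage_counts=pd.DataFrame(counts, columns=["stage", "survivors"]),
        class_codes=class_codes,
    )
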