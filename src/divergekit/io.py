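"""Readers, writers, and coordinate conversions for the on-disk formats.

All conversions between the package's internal GFF3-style coordinates
(1-based, inclusive) and BED (0-based, half-open) happen here and nowhere
else. FASTA goes through Biopython, GFF3 parsing through gffutils, VCF
reading through pysam; VCF and GFF3 writing are plain-text formatting so the
exported bytes are stable under write->read->write round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel

COUNTS_FORMAT_VERSION = "divergekit-counts-v1"
COUNTS_COLUMNS = ["chrom", "pos", "sample", "A", "C", "G", "T"]


# --- coordinates ----------------------------------------------------------

def gff_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def bed_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# --- FASTA ----------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# --- GFF3 gene models -----------------------------------------------------

def _cds_phases(model: GeneModel) -> list[int]:
    ivs = model.cds if model.strand == "+" else list(reversed(model.cds))
    phases, cum = [], 0
    for s, e in ivs:
        phases.append((3 - cum % 3) % 3)
        cum += e - s + 1
    return phases if model.strand == "+" else list(reversed(phases))


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Write gene/mRNA/exon/CDS/UTR features, 1-based inclusive, with phase."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id)):
            gid, mid = m.gene_id, f"{m.gene_id}.1"
            extra = f";subgenome={m.subgenome}" if m.subgenome else ""

            def row(ftype, s, e, phase=".", attrs=""):
                fh.write(
                    f"{m.chrom}\tdivergekit\t{ftype}\t{s}\t{e}\t.\t{m.strand}\t{phase}\t{attrs}\n"
                )

            row("gene", m.start, m.end, attrs=f"ID={gid}{extra}")
            row("mRNA", m.start, m.end, attrs=f"ID={mid};Parent={gid}")
            for i, (s, e) in enumerate(m.exons, 1):
                row("exon", s, e, attrs=f"ID={mid}.exon{i};Parent={mid}")
            for (s, e), ph in zip(m.cds, _cds_phases(m)):
                row("CDS", s, e, phase=str(ph), attrs=f"ID={mid}.cds;Parent={mid}")
            for s, e in m.utr5:
                row("five_prime_UTR", s, e, attrs=f"Parent={mid}")
            for s, e in m.utr3:
                row("three_prime_UTR", s, e, attrs=f"Parent={mid}")


def read_gff3(path: str) -> list[GeneModel]:
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons += [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds += [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        sub = gene.attributes.get("subgenome", [None])[0]
        models.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                exons=exons, cds=cds, subgenome=sub,
            )
        )
    return sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id))


# --- allele-count tables --------------------------------------------------

def write_counts(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {COUNTS_FORMAT_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False, columns=COUNTS_COLUMNS)


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df[COUNTS_COLUMNS]


# --- simple TSV helpers ---------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_subgenome_labels(path: str) -> dict[str, str]:
    df = read_tsv(path)
    return dict(zip(df["gene_id"], df["subgenome"]))


# --- BED transcript segments ----------------------------------------------

def write_bed_segments(segments: pd.DataFrame, path: str) -> None:
    """BED6 (0-based half-open): chrom, start, end, transcript_id, score, strand."""
    cols = ["chrom", "start", "end", "transcript_id", "score", "strand"]
    segments[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed_segments(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "transcript_id", "score", "strand"],
    )


# --- VCF ------------------------------------------------------------------

@dataclass
class VcfRecord:
    """One VCF site with per-sample genotype alleles and depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, str] = field(default_factory=dict)  # sample -> base
    depths: dict[str, int] = field(default_factory=dict)

    def _gt_index(self, allele: str) -> int:
        if allele == self.ref:
            return 0
        return 1 + self.alts.index(allele)


def write_vcf(records: list[VcfRecord], samples: list[str], path: str,
              contigs: dict[str, int] | None = None) -> None:
    """Write a VCF 4.2 file; records are sorted by (chrom, pos) before output."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=divergekit\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for r in records:
            cols = [r.chrom, str(r.pos), ".", r.ref, ",".join(r.alts) or ".",
                    ".", "PASS", ".", "GT:DP"]
            for s in samples:
                gt = r.genotypes.get(s)
                idx = "./." if gt is None else f"{r._gt_index(gt)}/{r._gt_index(gt)}"
                dp = r.depths.get(s)
                cols.append(f"{idx}:{dp if dp is not None else '.'}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str) -> tuple[list[VcfRecord], list[str]]:
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        records = []
        for rec in vf:
            alts = tuple(rec.alts or ())
            alleles = (rec.ref,) + alts
            genotypes, depths = {}, {}
            for s in samples:
                call = rec.samples[s]
                idx = call.get("GT", (None,))[0]
                if idx is not None:
                    genotypes[s] = alleles[idx]
                dp = call.get("DP")
                if dp is not None:
                    depths[s] = dp
            records.append(
                VcfRecord(rec.chrom, rec.pos, rec.ref, alts, genotypes, depths)
            )
    return records, samples


def vcf_body(path: str) -> str:
    """The non-header lines of a VCF file (for round-trip comparisons)."""
    with open(path) as fh:
        return "".join(line for line in fh if not line.startswith("#"))
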