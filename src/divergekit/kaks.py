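"""Ka/Ks estimation (NG86) and chromosome/sub-genome permutation tests.

Per-gene coding pairs are built by substituting each genotype's SNPs into
the reference and extracting the spliced CDS, so the two sequences are
aligned by construction. Ka and Ks are estimated with the Nei-Gojobori
counting method: per-codon synonymous-site fractions averaged over the two
sequences; codon differences resolved by averaging over all minimal
mutational pathways; and a Jukes-Cantor correction K = -(3/4) ln(1 - 4p/3)
applied to the proportions. Mutations to stop codons count as nonsynonymous
(the classical convention), so N + S equals the number of non-stop aligned
bases. A "weighted" companion method takes Ka/Ks from the Li-Wu-Luo (1985)
estimator instead, separating transitions from transversions by site
degeneracy with Kimura two-parameter corrections.

Chromosome-level inference compares each chromosome's median Ka/Ks with the
median of the rest of the genome against a permutation null in which genes
are randomly reassigned to chromosomes, either freely (gene counts
preserved) or stratified by sub-genome so each chromosome's LF/MF1/MF2
composition is preserved exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RefMismatchError
from .models import GeneModel
from .seq import BASES, CODON_TABLE, STOP_CODONS, extract_spliced, is_transition

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# genotype genome construction and CDS extraction
# --------------------------------------------------------------------------

def apply_variants(reference: dict[str, str], variants: pd.DataFrame) -> dict[str, str]:
    """Substitute SNPs (chrom, pos, ref, alt columns; 1-based) into a genome.

    Raises :class:`RefMismatchError` when a variant's stated reference base
    disagrees with the sequence.
    """
    arrays = {c: bytearray(s, "ascii") for c, s in reference.items()}
    for row in variants.itertuples(index=False):
        seq = arrays[row.chrom]
        have = chr(seq[row.pos - 1])
        if have != row.ref:
            raise RefMismatchError(
                f"{row.chrom}:{row.pos}: expected ref {row.ref!r}, sequence has {have!r}"
            )
        seq[row.pos - 1] = ord(row.alt)
    return {c: a.decode() for c, a in arrays.items()}


def extract_cds(genome: dict[str, str], model: GeneModel) -> str:
    """Strand-aware spliced CDS of one gene model from a genome sequence set."""
    return extract_spliced(genome, model.chrom, model.cds, model.strand)


@dataclass(frozen=True)
class CodingPair:
    """Aligned CDS sequences of one gene in the two genotypes."""

    gene_id: str
    cds_g1: str
    cds_g2: str

    def __post_init__(self) -> None:
        if len(self.cds_g1) != len(self.cds_g2):
            raise ValueError(f"{self.gene_id}: unequal CDS lengths")
        if len(self.cds_g1) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    def has_internal_stop(self) -> bool:
        for seq in (self.cds_g1, self.cds_g2):
            for i in range(0, len(seq) - 3, 3):
                if seq[i:i + 3] in STOP_CODONS:
                    return True
        return False


def coding_pairs(genome_g1: dict[str, str], genome_g2: dict[str, str],
                 models: list[GeneModel]) -> list[CodingPair]:
    """Extract per-gene CDS pairs, skipping incomplete/internal-stop models."""
    pairs = []
    for m in models:
        if m.incomplete:
            logger.info("skipping %s: incomplete CDS", m.gene_id)
            continue
        pair = CodingPair(m.gene_id, extract_cds(genome_g1, m),
                          extract_cds(genome_g2, m))
        if pair.has_internal_stop():
            logger.info("skipping %s: internal stop codon", m.gene_id)
            continue
        pairs.append(pair)
    return pairs


# --------------------------------------------------------------------------
# NG86
# --------------------------------------------------------------------------

def _codon_valid(codon: str) -> bool:
    return all(b in BASES for b in codon) and codon not in STOP_CODONS


def _syn_sites(codon: str) -> float:
    """Synonymous sites of one codon (0..3): the fraction of the nine
    single-base neighbour mutations that preserve the amino acid, times 3.
    Mutations to stop codons count as nonsynonymous, the classical NG86
    convention."""
    syn = 0
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1:]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == CODON_TABLE[codon]:
                syn += 1
    return syn / 3.0


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged with equal weight over all minimal mutational pathways; stops
    translate to '*', so a stop->stop step is synonymous and any step into
    or out of a stop is nonsynonymous.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []  # (syn_steps, nonsyn_steps)
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        pathways.append((syn, nonsyn))
    n = len(pathways)
    return (sum(s for s, _ in pathways) / n,
            sum(d for _, d in pathways) / n)


def _fold_class(codon: str, pos: int) -> int:
    """Degeneracy class of one codon position: 0-, 2-, or 4-fold.

    Counts how many of the three alternative bases are synonymous
    (mutations to stop codons count as nonsynonymous); 1 or 2 synonymous
    alternatives are lumped into the two-fold class as in Li et al. (1985).
    """
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if alt not in STOP_CODONS and CODON_TABLE[alt] == CODON_TABLE[codon]:
            syn += 1
    return {0: 0, 3: 4}.get(syn, 2)


def _pathway_ts_tv(c1: str, c2: str) -> dict[tuple[int, str], float]:
    """Transition/transversion difference counts per degeneracy class.

    Pathway-averaged like :func:`_pathway_diffs`; each step is attributed to
    the degeneracy class of the changed position in the codon the step
    starts from.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    out: dict[tuple[int, str], float] = {}
    if not diff_pos:
        return out
    orders = list(itertools.permutations(diff_pos))
    w = 1.0 / len(orders)
    for order in orders:
        cur = c1
        for p in order:
            kind = "ts" if is_transition(cur[p], c2[p]) else "tv"
            key = (_fold_class(cur, p), kind)
            out[key] = out.get(key, 0.0) + w
            cur = cur[:p] + c2[p] + cur[p + 1:]
    return out


def jukes_cantor(p: float) -> float | None:
    """K = -(3/4) ln(1 - 4p/3); None when the correction diverges (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsRecord:
    """Per-gene substitution-site bookkeeping and corrected rates."""

    gene_id: str
    N: float          # nonsynonymous sites
    S: float          # synonymous sites
    Nd: float         # nonsynonymous differences
    Sd: float         # synonymous differences
    Ka: float | None  # per-site nonsynonymous rate (JC-corrected)
    Ks: float | None  # per-site synonymous rate
    flagged: bool = False  # correction diverged

    @property
    def ratio(self) -> float | None:
        """Ka/Ks; None when Ks is 0/undefined or the correction diverged."""
        if self.Ka is None or self.Ks is None or self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def _valid_codon_pairs(pair: CodingPair):
    for i in range(0, len(pair.cds_g1), 3):
        c1, c2 = pair.cds_g1[i:i + 3], pair.cds_g2[i:i + 3]
        if _codon_valid(c1) and _codon_valid(c2):
            yield c1, c2


def _k2p_components(p: float, q: float) -> tuple[float | None, float | None]:
    """Kimura two-parameter transition (A) and transversion (B) distances."""
    a = b = None
    if 1 - 2 * p - q > 0 and 1 - 2 * q > 0:
        a = 0.5 * math.log(1 / (1 - 2 * p - q)) - 0.25 * math.log(1 / (1 - 2 * q))
    if 1 - 2 * q > 0:
        b = 0.5 * math.log(1 / (1 - 2 * q))
    return a, b


def _lwl85_rates(pair: CodingPair) -> tuple[float | None, float | None]:
    """Li-Wu-Luo (1985) Ka/Ks with transition/transversion separation.

    Sites are classified by degeneracy (0-, 2-, 4-fold, averaged over both
    sequences); transitional (P) and transversional (Q) difference
    proportions per class get Kimura two-parameter corrections A and B, and
        Ks = 3 [L2 A2 + L4 (A4 + B4)] / (L2 + 3 L4)
        Ka = 3 [L2 B2 + L0 (A0 + B0)] / (2 L2 + 3 L0)
    """
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    diffs: dict[tuple[int, str], float] = {}
    for c1, c2 in _valid_codon_pairs(pair):
        for p in range(3):
            L[_fold_class(c1, p)] += 0.5
            L[_fold_class(c2, p)] += 0.5
        for key, v in _pathway_ts_tv(c1, c2).items():
            diffs[key] = diffs.get(key, 0.0) + v
    A, B = {}, {}
    for fold in (0, 2, 4):
        p = diffs.get((fold, "ts"), 0.0) / L[fold] if L[fold] else 0.0
        q = diffs.get((fold, "tv"), 0.0) / L[fold] if L[fold] else 0.0
        A[fold], B[fold] = _k2p_components(p, q)
    ks = ka = None
    if None not in (A[2], A[4], B[4]) and (L[2] + 3 * L[4]) > 0:
        ks = 3 * (L[2] * A[2] + L[4] * (A[4] + B[4])) / (L[2] + 3 * L[4])
    if None not in (B[2], A[0], B[0]) and (2 * L[2] + 3 * L[0]) > 0:
        ka = 3 * (L[2] * B[2] + L[0] * (A[0] + B[0])) / (2 * L[2] + 3 * L[0])
    return ka, ks


def compute_kaks(pair: CodingPair, method: str = "NG86") -> KaKsRecord:
    """Ka/Ks for one aligned CDS pair.

    ``method="NG86"`` is the unweighted Nei-Gojobori estimator with
    Jukes-Cantor correction. ``method="weighted"`` keeps the same site and
    difference bookkeeping in the record but takes Ka and Ks from the
    Li-Wu-Luo (1985) estimator, which separates transitions from
    transversions by site degeneracy class and applies Kimura two-parameter
    corrections. Codons containing ambiguous bases, or that are stop codons
    in either sequence, are skipped in both sequences with site totals
    adjusted.
    """
    if method not in ("NG86", "weighted"):
        raise ValueError(f"unknown method {method!r}")
    if pair.has_internal_stop():
        raise ValueError(f"{pair.gene_id}: internal stop codon")
    s_sites = n_sites = sd = nd = 0.0
    for c1, c2 in _valid_codon_pairs(pair):
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        d_s, d_n = _pathway_diffs(c1, c2)
        sd += d_s
        nd += d_n
    if method == "weighted":
        ka, ks = _lwl85_rates(pair)
    else:
        ps = sd / s_sites if s_sites > 0 else 0.0
        pn = nd / n_sites if n_sites > 0 else 0.0
        ks = jukes_cantor(ps)
        ka = jukes_cantor(pn)
    flagged = ka is None or ks is None
    if flagged:
        logger.info("%s: distance correction diverged", pair.gene_id)
    return KaKsRecord(pair.gene_id, n_sites, s_sites, nd, sd, ka, ks, flagged)


def records_to_dataframe(records: list[KaKsRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "N": r.N, "S": r.S, "Nd": r.Nd, "Sd": r.Sd,
        "Ka": np.nan if r.Ka is None else r.Ka,
        "Ks": np.nan if r.Ks is None else r.Ks,
        "ratio": np.nan if r.ratio is None else r.ratio,
    } for r in records])


# --------------------------------------------------------------------------
# sub-genome comparison
# --------------------------------------------------------------------------

def _median_diff_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int,
                        rng: np.random.Generator) -> float:
    """Two-sided label-permutation p-value for median(a) - median(b)."""
    obs = np.median(a) - np.median(b)
    pooled = np.concatenate([a, b])
    na = len(a)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        null = np.median(pooled[:na]) - np.median(pooled[na:])
        if abs(null) >= abs(obs):
            count += 1
    return (count + 1) / (n_perm + 1)


def compare_subgenomes(table: pd.DataFrame, n_perm: int = 10_000,
                       seed: int = 0) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sub-genome median Ka/Ks and pairwise permutation p-values.

    ``table`` needs ``subgenome`` and ``ratio`` columns; genes with undefined
    (NaN) ratios are dropped with a log entry. Raises on an empty label class.
    """
    t = table.dropna(subset=["ratio"])
    if len(t) < len(table):
        logger.info("dropping %d genes with undefined Ka/Ks ratio",
                    len(table) - len(t))
    labels = sorted(t["subgenome"].unique())
    groups = {lab: t.loc[t["subgenome"] == lab, "ratio"].to_numpy() for lab in labels}
    for lab in ("LF", "MF1", "MF2"):
        if lab not in groups or len(groups[lab]) == 0:
            raise ValueError(f"empty sub-genome class {lab!r}")
    medians = pd.Series({lab: float(np.median(v)) for lab, v in groups.items()},
                        name="median_ratio")
    rng = np.random.default_rng(seed)
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        p = _median_diff_pvalue(groups[la], groups[lb], n_perm, rng)
        rows.append((la, lb, float(np.median(groups[la]) - np.median(groups[lb])), p))
    pvals = pd.DataFrame(rows, columns=["label_a", "label_b", "median_diff", "p_value"])
    return medians, pvals


# --------------------------------------------------------------------------
# chromosome permutation test
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Chromosome-vs-rest median Ka/Ks difference against a permutation null.

    ``significant`` follows the 95% exceedance rule with ties counting as
    exceeded: the observed |difference| must be >= |null difference| in at
    least 95% of permutations.
    """

    chromosome: str
    observed_diff: float
    null_diffs: np.ndarray
    n_genes: int

    @property
    def exceed_fraction(self) -> float:
        return float(np.mean(np.abs(self.null_diffs) <= abs(self.observed_diff)))

    @property
    def significant(self) -> bool:
        return self.exceed_fraction >= 0.95


def _shuffled_matrix(values: np.ndarray, n_perm: int,
                     rng: np.random.Generator,
                     strata: np.ndarray | None) -> np.ndarray:
    """(n_perm, n) matrix of permuted values; permutations are within-stratum
    when ``strata`` is given (preserving each chromosome's per-stratum
    counts, since gene positions keep their chromosome and stratum)."""
    n = len(values)
    out = np.empty((n_perm, n), dtype=float)
    if strata is None:
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        out[:] = values[order]
    else:
        for lab in np.unique(strata):
            idx = np.nonzero(strata == lab)[0]
            order = np.argsort(rng.random((n_perm, len(idx))), axis=1)
            out[:, idx] = values[idx][order]
    return out


def chromosome_permutation_test(table: pd.DataFrame, n_perm: int = 1000,
                                mode: str = "unconstrained",
                                seed: int = 0) -> list[PermutationResult]:
    """Permutation test of per-chromosome median Ka/Ks against the rest.

    ``table`` needs chrom and ratio columns (plus subgenome for
    ``mode="subgenome_preserving"``). Genes with undefined ratios are
    dropped; chromosomes left with fewer than 2 ratios are excluded with a
    warning. In the unconstrained mode genes are randomly reassigned to
    chromosomes keeping gene counts; in the constrained mode reassignment is
    stratified by sub-genome so every chromosome keeps its exact LF/MF1/MF2
    composition in every permutation.
    """
    if mode not in ("unconstrained", "subgenome_preserving"):
        raise ValueError(f"unknown mode {mode!r}")
    t = table.dropna(subset=["ratio"])
    keep = t.groupby("chrom")["ratio"].transform("size") >= 2
    dropped = sorted(set(t.loc[~keep, "chrom"]))
    if dropped:
        logger.warning("excluding chromosomes with < 2 defined ratios: %s", dropped)
    t = t.loc[keep]
    values = t["ratio"].to_numpy(dtype=float)
    chroms = t["chrom"].to_numpy()
    strata = None
    if mode == "subgenome_preserving":
        if "subgenome" not in t.columns:
            raise ValueError("subgenome column required for constrained mode")
        strata = t["subgenome"].to_numpy()

    rng = np.random.default_rng(seed)
    shuffled = _shuffled_matrix(values, n_perm, rng, strata)
    results = []
    for chrom in sorted(pd.unique(chroms)):
        mask = chroms == chrom
        obs = float(np.median(values[mask]) - np.median(values[~mask]))
        null = (np.median(shuffled[:, mask], axis=1)
                - np.median(shuffled[:, ~mask], axis=1))
        results.append(PermutationResult(str(chrom), obs, null, int(mask.sum())))
    return results


def permutation_report(results: list[PermutationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chromosome": r.chromosome, "n_genes": r.n_genes,
        "observed_diff": r.observed_diff,
        "exceed_fraction": r.exceed_fraction,
        "significant": r.significant,
    } for r in results])
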