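"""NG86 estimation, genotype genome construction, and permutation inference."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from divergekit.errors import RefMismatchError
from divergekit.kaks import (CodingPair, apply_variants,
                             chromosome_permutation_test, coding_pairs,
                             compare_subgenomes, compute_kaks, extract_cds,
                             records_to_dataframe, _shuffled_matrix)
from divergekit.models import GeneModel
from divergekit.seq import SENSE_CODONS, revcomp
from divergekit.simulate import simulate_kaks_table

warnings.filterwarnings("ignore", category=Warning, module="Bio")


class TestApplyVariants:
    def test_empty_variant_list_is_identity(self):
        ref = {"c": "ACGTACGT"}
        assert apply_variants(ref, pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])) == ref

    def test_single_substitution_changes_exactly_one_base(self):
        out = apply_variants({"c": "ACGT"}, pd.DataFrame(
            [{"chrom": "c", "pos": 3, "ref": "G", "alt": "T"}]))
        assert out == {"c": "ACTT"}

    def test_reference_mismatch_names_the_position(self):
        with pytest.raises(RefMismatchError, match="c:3"):
            apply_variants({"c": "ACGT"}, pd.DataFrame(
                [{"chrom": "c", "pos": 3, "ref": "A", "alt": "T"}]))

    def test_apply_then_rediff_recovers_variants(self, genome_models, planted):
        from divergekit.simulate import genome_diffs
        genome, _ = genome_models
        truth, mutated = planted["G1"]
        rebuilt = apply_variants(genome, truth[["chrom", "pos", "ref", "alt"]])
        assert rebuilt == mutated
        diffs = genome_diffs(genome, rebuilt)
        assert diffs.merge(truth, on=["chrom", "pos", "ref", "alt"]).shape[0] == len(truth)


class TestExtractCds:
    def test_single_exon_plus_strand_is_a_substring(self):
        genome = {"c": "AAATGGGCTAACCC"}
        m = GeneModel("g", "c", "+", exons=[(3, 11)], cds=[(3, 11)])
        assert extract_cds(genome, m) == "ATGGGCTAA"

    def test_two_exon_minus_strand_matches_hand_construction(self):
        genome = {"c": "TTACGGTCCATGAAT"}
        m = GeneModel("g", "c", "-", exons=[(3, 6), (10, 12)], cds=[(3, 6), (10, 12)])
        # genomic pieces: ACGG + ATG; minus strand => revcomp("ACGGATG")
        assert extract_cds(genome, m) == revcomp("ACGGATG") == "CATCCGT"

    def test_out_of_bounds_interval_raises(self):
        genome = {"c": "ACGT"}
        m = GeneModel("g", "c", "+", exons=[(2, 9)], cds=[(2, 9)])
        with pytest.raises(IndexError):
            extract_cds(genome, m)

    def test_variant_genome_extraction_differs_only_at_planted_cds_sites(
            self, genome_models, planted):
        genome, models = genome_models
        truth, mutated = planted["G1"]
        planted_cds = set(zip(truth.chrom, truth.pos))
        for m in models[:20]:
            a, b = extract_cds(genome, m), extract_cds(mutated, m)
            diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
            for off in diffs:
                positions = [p for s, e in m.cds for p in range(s, e + 1)]
                if m.strand == "-":
                    positions = positions[::-1]
                assert (m.chrom, positions[off]) in planted_cds


class TestNG86:
    def test_identical_sequences_have_zero_rates_and_undefined_ratio(self):
        s = "ATGGGAGCT"
        rec = compute_kaks(CodingPair("g", s, s))
        assert rec.Nd == rec.Sd == 0 and rec.Ka == rec.Ks == 0.0
        assert rec.ratio is None

    def test_hand_computed_toy_matches_to_1e9(self):
        """30 codons, one third-position GGA->GGG synonymous difference.

        By codon degeneracy: ATG contributes 0 synonymous sites, GGA and GGG
        1.0 each (third position four-fold, first two zero-fold), so
        S = 29, N = 61, Sd = 1, Nd = 0, pS = 1/29, and
        Ks = -(3/4) ln(1 - 4/(3*29)).
        """
        s1 = "ATG" + "GGA" * 29
        s2 = "ATG" + "GGA" * 28 + "GGG"
        rec = compute_kaks(CodingPair("toy", s1, s2))
        assert rec.S == pytest.approx(29.0, abs=1e-9)
        assert rec.N == pytest.approx(61.0, abs=1e-9)
        assert (rec.Sd, rec.Nd) == (1.0, 0.0)
        ks_hand = -0.75 * math.log(1 - 4 / (3 * 29))
        assert rec.Ks == pytest.approx(ks_hand, abs=1e-9)
        assert rec.Ka == 0.0 and rec.ratio == 0.0

    def test_symmetry_and_site_conservation(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            c1 = [SENSE_CODONS[i] for i in rng.integers(61, size=40)]
            c2 = [SENSE_CODONS[i] if rng.random() > 0.2 else
                  SENSE_CODONS[rng.integers(61)] for i in rng.integers(61, size=40)]
            s1, s2 = "".join(c1), "".join(c2)
            a = compute_kaks(CodingPair("g", s1, s2))
            b = compute_kaks(CodingPair("g", s2, s1))
            assert (a.N, a.S, a.Nd, a.Sd) == (b.N, b.S, b.Nd, b.Sd)
            assert a.N + a.S == pytest.approx(len(s1))

    def test_matches_independent_reference_implementation(self):
        """Dual-route check against Biopython's NG86 (not used internally)."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(41)
        for _ in range(20):
            c1 = ["ATG"] + [SENSE_CODONS[i] for i in rng.integers(61, size=50)]
            c2 = list(c1)
            for _ in range(8):
                c2[int(rng.integers(1, 51))] = SENSE_CODONS[int(rng.integers(61))]
            s1, s2 = "".join(c1), "".join(c2)
            rec = compute_kaks(CodingPair("g", s1, s2))
            dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
            assert rec.Ka == pytest.approx(dn, abs=1e-9)
            assert rec.Ks == pytest.approx(ds, abs=1e-9)

    def test_weighted_method_matches_hand_li_wu_luo_computation(self):
        # 30 codons, one GGA->GGG third-position transition. Degeneracy:
        # ATG contributes three zero-fold positions, GGA/GGG two zero-fold
        # and one four-fold, so L0 = 61, L2 = 0, L4 = 29, P4 = 1/29, and
        # Ks = A4 = (1/2) ln(1 / (1 - 2/29)) with Ka = 0.
        s1 = "ATG" + "GGA" * 29
        s2 = "ATG" + "GGA" * 28 + "GGG"
        rec = compute_kaks(CodingPair("g", s1, s2), method="weighted")
        assert rec.Ks == pytest.approx(0.5 * math.log(1 / (1 - 2 / 29)), abs=1e-12)
        assert rec.Ka == 0.0

    def test_weighted_method_departs_from_ng86_under_transition_bias(self):
        # transitions concentrated at four-fold sites: LWL85 corrects with
        # K2P within the class, NG86 pools everything through one JC
        s1 = "ATG" + "CTA" * 40
        s2 = "ATG" + ("CTG" * 20 + "CTA" * 20)
        plain = compute_kaks(CodingPair("g", s1, s2), method="NG86")
        weighted = compute_kaks(CodingPair("g", s1, s2), method="weighted")
        assert weighted.Ks != pytest.approx(plain.Ks, abs=1e-6)
        assert (plain.Sd, plain.Nd) == (weighted.Sd, weighted.Nd)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            CodingPair("g", "ATGAAA", "ATG")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            compute_kaks(CodingPair("g", "ATGTAAAAA", "ATGTAAAAA"))

    def test_ambiguous_codons_skipped_in_both_sequences(self):
        rec = compute_kaks(CodingPair("g", "ATGNNNGGA", "ATGAAAGGG"))
        assert rec.N + rec.S == pytest.approx(6.0)  # the N codon dropped


def test_coding_pairs_from_planted_genomes_have_no_stops(genome_models, planted):
    genome, models = genome_models
    (_, g1), (_, g2) = planted.values()
    pairs = coding_pairs(g1, g2, models)
    assert len(pairs) == len(models)
    recs = [compute_kaks(p) for p in pairs]
    df = records_to_dataframe(recs)
    # sites partition every aligned non-stop base (the terminal stop codon
    # is excluded from the site counts)
    assert (df.N + df.S).round(6).eq([len(p.cds_g1) - 3 for p in pairs]).all()


class TestSubgenomeComparison:
    def test_identical_ratios_give_pvalues_near_one(self):
        tab = pd.DataFrame({"subgenome": ["LF", "MF1", "MF2"] * 30,
                            "ratio": [0.3] * 90})
        med, pv = compare_subgenomes(tab, n_perm=200, seed=0)
        assert (med == 0.3).all()
        assert (pv.p_value > 0.9).all()

    def test_planted_lf_shift_is_detected(self):
        tab = simulate_kaks_table(label_shift={"LF": 0.5}, seed=9)
        _, pv = compare_subgenomes(tab, n_perm=2000, seed=1)
        lf_rows = pv[(pv.label_a == "LF") | (pv.label_b == "LF")]
        assert (lf_rows.p_value < 0.05).all()

    def test_empty_label_class_raises(self):
        tab = pd.DataFrame({"subgenome": ["LF", "MF1"] * 10, "ratio": [0.2] * 20})
        with pytest.raises(ValueError):
            compare_subgenomes(tab, n_perm=50)


class TestChromosomePermutation:
    def test_identical_ratios_give_zero_diffs_nothing_significant(self):
        tab = pd.DataFrame({"chrom": ["c1"] * 20 + ["c2"] * 20, "ratio": [0.4] * 40})
        for r in chromosome_permutation_test(tab, n_perm=100, seed=0):
            assert r.observed_diff == 0.0
            assert not r.significant or r.exceed_fraction == 1.0  # all-tie degenerate

    def test_planted_shift_detected_and_null_calibrated(self):
        hits = 0
        for rep in range(20):
            tab = simulate_kaks_table(chrom_shift={"chr01": 2.0}, seed=6000 + rep)
            res = chromosome_permutation_test(tab, n_perm=200, seed=rep)
            hits += next(r for r in res if r.chromosome == "chr01").significant
        assert hits >= 19

    def test_constrained_permutations_preserve_stratum_multisets(self):
        tab = simulate_kaks_table(seed=5)
        values = tab.ratio.to_numpy()
        strata = tab.subgenome.to_numpy()
        rng = np.random.default_rng(0)
        shuffled = _shuffled_matrix(values, 50, rng, strata)
        for lab in ("LF", "MF1", "MF2"):
            idx = strata == lab
            want = np.sort(values[idx])
            for row in range(0, 50, 7):
                assert np.allclose(np.sort(shuffled[row, idx]), want)
        # positions keep their (chromosome, stratum), so per-chromosome
        # label counts are preserved exactly in every permutation
        counts = tab.groupby(["chrom", "subgenome"]).size()
        assert counts.sum() == len(tab)

    def test_sparse_chromosomes_are_excluded_with_warning(self, caplog):
        tab = pd.DataFrame({"chrom": ["c1"] * 30 + ["c2"],
                            "ratio": list(np.linspace(0.1, 1.0, 30)) + [0.5]})
        res = chromosome_permutation_test(tab, n_perm=50, seed=0)
        assert [r.chromosome for r in res] == ["c1"]

    def test_fixed_seed_reproduces_null_distributions(self):
        tab = simulate_kaks_table(seed=8)
        a = chromosome_permutation_test(tab, n_perm=100, seed=3)
        b = chromosome_permutation_test(tab, n_perm=100, seed=3)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.null_diffs, rb.null_diffs)
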