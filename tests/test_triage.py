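"""Transcript triage: stages, thresholds, class codes, truth recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divergekit.kaks import extract_cds
from divergekit.models import GeneModel
from divergekit.seq import revcomp
from divergekit.triage import (AssembledTranscript, best_isoform,
                               build_transcript_model, classify_transcripts,
                               find_orfs, is_chimera, match_known,
                               merge_segments, remove_exact_duplicates,
                               select_representative, span_filter,
                               triage_pipeline)


def tx(tid, seq="ACGT" * 50, locus=None, coverage=1.0):
    return AssembledTranscript(tid, seq, locus or tid, coverage)


class TestRepresentative:
    def test_singleton_group_returns_itself(self):
        t = tx("a")
        kept, dropped = select_representative([t])
        assert kept == [t] and dropped == []

    def test_highest_coverage_wins(self):
        a, b = tx("a", locus="L", coverage=10), tx("b", locus="L", coverage=50)
        kept, _ = select_representative([a, b])
        assert kept == [b]

    def test_length_breaks_coverage_ties(self):
        a = tx("a", seq="A" * 900, locus="L", coverage=10)
        b = tx("b", seq="A" * 1200, locus="L", coverage=10)
        kept, _ = select_representative([a, b])
        assert kept == [b]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 100), st.integers(10, 500)),
                    min_size=1, max_size=8))
    def test_winner_matches_argmax_oracle(self, group):
        txs = [tx(f"t{i}", seq="A" * ln, locus="L", coverage=cov)
               for i, (cov, ln) in enumerate(group)]
        kept, _ = select_representative(txs)
        best = max(txs, key=lambda t: (t.coverage, len(t.sequence),
                                       [-ord(c) for c in t.transcript_id]))
        assert kept[0].coverage == best.coverage
        assert len(kept[0].sequence) == len(best.sequence)


class TestOrfs:
    def test_orf_below_minimum_protein_length_is_rejected(self):
        # Met + 48 residues = 49 aa, one short of the cutoff
        seq = "CC" + "ATG" + "GGA" * 48 + "TAA" + "CC"
        orfs, primary = find_orfs("t", seq)
        assert orfs == [] and primary is None
        orfs, _ = find_orfs("t", seq, min_protein_length=49)
        assert len(orfs) == 1 and orfs[0].protein_length == 49

    def test_no_atg_means_no_orfs(self):
        seq = "".join("CAG"[i % 3] for i in range(400))
        assert find_orfs("t", seq)[0] == []

    def test_orf_interval_includes_stop_codon(self):
        seq = "A" + "ATG" + "CCT" * 60 + "TGA"
        (orf,), primary = find_orfs("t", seq)
        assert orf.start == 1 and orf.end == 1 + 3 * 62
        assert orf.end - orf.start == 3 * (orf.protein_length + 1)

    def test_three_orf_toy_matches_brute_force_scan(self):
        rng = np.random.default_rng(47)
        parts = ["ATG" + "GCT" * 55 + "TAA", "T",
                 "ATG" + "GAA" * 70 + "TAG", "GG",
                 revcomp("ATG" + "CCA" * 60 + "TGA")]
        seq = "".join(parts)

        def brute(seq, min_aa=50):
            found = set()
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for start in range(len(s) - 2):
                    if s[start:start + 3] != "ATG":
                        continue
                    for end in range(start + 3, len(s) - 2, 3):
                        codon = s[end:end + 3]
                        if codon in ("TAA", "TAG", "TGA"):
                            if (end - start) // 3 >= min_aa:
                                # first-ATG convention: keep only if no
                                # upstream in-frame ATG without a stop between
                                up = start - 3
                                first = True
                                while up >= 0:
                                    c = s[up:up + 3]
                                    if c in ("TAA", "TAG", "TGA"):
                                        break
                                    if c == "ATG":
                                        first = False
                                        break
                                    up -= 3
                                if first:
                                    found.add((strand, start, end + 3))
                            break
            return found

        orfs, primary = find_orfs("t", seq)
        assert {(o.strand, o.start, o.end) for o in orfs} == brute(seq)
        assert len(orfs) == 3
        assert primary.protein_length == 71  # Met + 70 residues


class TestMatchKnown:
    @pytest.fixture(scope="class")
    def cds_set(self, genome_models):
        genome, models = genome_models
        return genome, models, {m.gene_id: extract_cds(genome, m) for m in models}

    def test_exact_cds_copy_is_known(self, cds_set):
        _, models, cds = cds_set
        t = tx("t", seq=cds[models[0].gene_id])
        known, novel = match_known([t], cds)
        assert known == [t] and novel == []

    def test_reverse_complement_copy_is_known(self, cds_set):
        _, models, cds = cds_set
        t = tx("t", seq=revcomp(cds[models[1].gene_id]))
        known, _ = match_known([t], cds)
        assert known == [t]

    def test_random_sequence_is_candidate_novel(self, cds_set):
        _, _, cds = cds_set
        rng = np.random.default_rng(53)
        t = tx("t", seq="".join("ACGT"[i] for i in rng.integers(0, 4, 600)))
        known, novel = match_known([t], cds)
        assert novel == [t]

    @pytest.mark.parametrize("rate,expect_known", [(0.03, True), (0.10, False)])
    def test_identity_threshold_separates_divergence_levels(self, cds_set,
                                                            rate, expect_known):
        _, models, cds = cds_set
        rng = np.random.default_rng(59)
        seq = list(cds[models[2].gene_id])
        n_mut = int(round(rate * len(seq)))
        for i in rng.choice(len(seq), size=n_mut, replace=False):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        known, novel = match_known([tx("t", seq="".join(seq))], cds)
        assert bool(known) is expect_known

    def test_short_queries_below_aligned_floor_never_match(self, cds_set):
        _, models, cds = cds_set
        t = tx("t", seq=cds[models[0].gene_id][:80])  # < 100 bp floor
        known, novel = match_known([t], cds)
        assert novel == [t]


class TestSegments:
    def test_single_segment_is_single_exon(self):
        m = build_transcript_model("t", [("c", 100, 200, "+")])
        assert m.exon_chain == [("c", 100, 200)]

    def test_overlapping_segments_merge(self):
        m = build_transcript_model("t", [("c", 100, 200, "+"), ("c", 150, 250, "+")])
        assert m.exon_chain == [("c", 100, 250)]

    def test_empty_segment_list_raises(self):
        with pytest.raises(ValueError):
            build_transcript_model("t", [])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)),
                    min_size=1, max_size=10))
    def test_merged_chain_equals_interval_union_oracle(self, raw):
        segs = [("c", s, s + ln, "+") for s, ln in raw]
        chain = merge_segments(segs)
        covered = set()
        for _, s, e, _ in segs:
            covered |= set(range(s, e))
        from_chain = set()
        for _, s, e in chain:
            assert s < e
            from_chain |= set(range(s, e))
        assert from_chain == covered
        starts = [s for _, s, _ in chain]
        assert starts == sorted(starts)


class TestChimerasAndSpan:
    def test_single_chromosome_is_not_chimera(self):
        m = build_transcript_model("t", [("c1", 0, 300, "+"), ("c1", 400, 700, "+")])
        assert not is_chimera(m)

    def test_split_halves_on_two_chromosomes_is_chimera(self):
        m = build_transcript_model("t", [("c1", 0, 300, "+"), ("c2", 0, 300, "+")])
        assert is_chimera(m)

    @pytest.mark.parametrize("second_len,expected", [(40, False), (49, False),
                                                     (50, True), (120, True)])
    def test_minimum_secondary_segment_threshold(self, second_len, expected):
        m = build_transcript_model(
            "t", [("c1", 0, 300, "+"), ("c2", 0, second_len, "+")])
        assert is_chimera(m) is expected

    @pytest.mark.parametrize("span,kept", [(9_999, True), (10_000, True),
                                           (10_001, False)])
    def test_span_boundary_follows_strictly_greater_rule(self, span, kept):
        m = build_transcript_model("t", [("c", 0, 100, "+"),
                                         ("c", span - 100, span, "+")])
        retained, dropped = span_filter([m])
        assert (m in retained) is kept

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 30_000), st.integers(50, 400)),
                    min_size=1, max_size=6))
    def test_span_decision_equals_direct_computation(self, raw):
        segs = [("c", s, s + ln, "+") for s, ln in raw]
        m = build_transcript_model("t", segs)
        lo = min(s for _, s, _, _ in segs)
        hi = max(e for _, _, e, _ in segs)
        assert m.genomic_span() == hi - lo
        retained, _ = span_filter([m])
        assert (m in retained) == (hi - lo <= 10_000)


class TestBestIsoform:
    def test_longer_transcript_wins(self):
        a = build_transcript_model("a", [("c", 0, 500, "+")])
        b = build_transcript_model("b", [("c", 100, 900, "+")])
        kept, dropped = best_isoform([a, b], {"a": 500, "b": 800})
        assert kept == [b] and dropped == [a]

    def test_singleton_locus_is_kept(self):
        a = build_transcript_model("a", [("c", 0, 500, "+")])
        kept, _ = best_isoform([a], {"a": 500})
        assert kept == [a]

    def test_disjoint_loci_each_keep_one(self):
        ms = [build_transcript_model(t, [("c", s, s + 100, "+")])
              for t, s in (("a", 0), ("b", 1000), ("c", 2000))]
        kept, _ = best_isoform(ms, {"a": 100, "b": 100, "c": 100})
        assert len(kept) == 3


class TestClassCodes:
    @pytest.fixture(scope="class")
    def reference(self):
        return [GeneModel("g1", "c", "+", exons=[(101, 200), (301, 400), (501, 600)],
                          cds=[(121, 200), (301, 400), (501, 540)])]

    def chain(self, ivs, strand="+"):
        return build_transcript_model("t", [("c", s, e, strand) for s, e in ivs])

    def test_identical_exon_chain_is_exact(self, reference):
        t = self.chain([(100, 200), (300, 400), (500, 600)])
        assert classify_transcripts([t], reference)["t"] == "="

    def test_contained_fragment_is_c(self, reference):
        t = self.chain([(320, 380)])
        assert classify_transcripts([t], reference)["t"] == "c"

    def test_partial_junction_share_is_j(self, reference):
        t = self.chain([(300, 400), (500, 650)])
        assert classify_transcripts([t], reference)["t"] == "j"

    def test_same_strand_overlap_without_junctions_is_o(self, reference):
        t = self.chain([(150, 350)])
        assert classify_transcripts([t], reference)["t"] == "o"

    def test_opposite_strand_overlap_is_x(self, reference):
        t = self.chain([(150, 250)], strand="-")
        assert classify_transcripts([t], reference)["t"] == "x"

    def test_fully_intronic_transcript_is_i(self, reference):
        t = self.chain([(220, 280)])
        assert classify_transcripts([t], reference)["t"] == "i"

    def test_gene_desert_transcript_is_u(self, reference):
        t = self.chain([(5_000, 5_400)])
        assert classify_transcripts([t], reference)["t"] == "u"


class TestPipeline:
    def test_annotation_copies_yield_empty_novel_set(self, genome_models):
        from divergekit.seq import extract_spliced
        genome, models = genome_models
        cds = {m.gene_id: extract_cds(genome, m) for m in models}
        txs, segs = [], []
        for i, m in enumerate(models[:5]):
            seq = extract_spliced(genome, m.chrom, m.exons, m.strand)
            txs.append(tx(f"t{i}", seq=seq))
            segs += [{"chrom": m.chrom, "start": s - 1, "end": e,
                      "transcript_id": f"t{i}", "score": 0, "strand": m.strand}
                     for s, e in m.exons]
        res = triage_pipeline(txs, pd.DataFrame(segs), cds, models)
        assert res.novel == []
        assert all(d == "known" for d in res.dispositions.values())

    def test_synthetic_truth_recovered_exactly(self, genome_models, default_config):
        from divergekit.simulate import simulate_transcript_set
        genome, models = genome_models
        txs, segs, truth = simulate_transcript_set(genome, models, default_config)
        cds = {m.gene_id: extract_cds(genome, m) for m in models}
        res = triage_pipeline(txs, segs, cds, models)
        intended = set(truth[truth.intended_class == "novel"].transcript_id)
        assert {t.transcript_id for t in res.novel} == intended
        # each designed failure mode dies at its designated stage
        by_class = dict(zip(truth.transcript_id, truth.intended_class))
        for tid, disposition in res.dispositions.items():
            want = by_class[tid]
            if want in ("exact", "fragment"):
                want = "known"
            assert disposition == want, tid
        # novels in intergenic space carry class code u
        assert set(res.class_codes.values()) == {"u"}

    def test_stage_counts_never_increase(self, genome_models, default_config):
        from divergekit.simulate import simulate_transcript_set
        genome, models = genome_models
        txs, segs, _ = simulate_transcript_set(genome, models, default_config)
        cds = {m.gene_id: extract_cds(genome, m) for m in models}
        res = triage_pipeline(txs, segs, cds, models)
        counts = res.stage_counts.survivors.tolist()
        assert counts == sorted(counts, reverse=True)

    def test_every_transcript_has_exactly_one_disposition(self, genome_models,
                                                          default_config):
        from divergekit.simulate import simulate_transcript_set
        genome, models = genome_models
        txs, segs, _ = simulate_transcript_set(genome, models, default_config)
        cds = {m.gene_id: extract_cds(genome, m) for m in models}
        res = triage_pipeline(txs, segs, cds, models)
        assert set(res.dispositions) == {t.transcript_id for t in txs}

    def test_classification_is_input_order_invariant(self, genome_models,
                                                     default_config):
        from divergekit.simulate import simulate_transcript_set
        genome, models = genome_models
        txs, segs, _ = simulate_transcript_set(genome, models, default_config)
        cds = {m.gene_id: extract_cds(genome, m) for m in models}
        fwd = triage_pipeline(txs, segs, cds, models)
        rev = triage_pipeline(txs[::-1], segs.iloc[::-1], cds, models)
        assert fwd.dispositions == rev.dispositions


def test_exact_duplicate_removal_keeps_first_id():
    a, b, c = tx("a", seq="ACGT" * 30), tx("b", seq="ACGT" * 30), tx("c", seq="TTTT" * 30)
    kept, dropped = remove_exact_duplicates([b, c, a])
    assert {t.transcript_id for t in kept} == {"a", "c"}
    assert [t.transcript_id for t in dropped] == ["b"]
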