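import numpy as np
import pytest

from baitforge.core import Alignment, RunConfig, SeqRecord
from baitforge.locus_selection import (
    GeneModel,
    TargetLocus,
    cluster_and_intersect,
    copy_number_check,
    dedupe_panels,
    filter_candidate_genes,
    infer_gene_model,
    match_transcript_to_genome,
    pair_identity,
    revcomp,
    select_panel_references,
)
from baitforge.synthetic_data import mutate_k80, random_sequence


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSplicedMatching:
    def test_exact_substring_single_block(self):
        rng = _rng(1)
        contig = SeqRecord("c", random_sequence(rng, 3000), dataset="genome")
        t = SeqRecord("t", contig.sequence[500:1100])
        matches = match_transcript_to_genome(t, [contig], 0.92)
        assert len(matches) == 1
        m = matches[0]
        assert m.identity == 1.0
        assert m.blocks == [(500, 1100, 0, 600)]
        assert m.strand == "+"

    def test_planted_intron_two_abutting_blocks(self):
        # transcript halves flank a planted 300 bp intron; the oracle is
        # the construction itself: each half aligns exactly to its
        # genomic exon, so two blocks whose transcript ranges abut
        rng = _rng(2)
        exon1 = random_sequence(rng, 400)
        intron = random_sequence(rng, 300)
        exon2 = random_sequence(rng, 350)
        flank = random_sequence(rng, 500)
        contig = SeqRecord("c", flank + exon1 + intron + exon2 + flank)
        t = SeqRecord("t", exon1 + exon2)
        matches = match_transcript_to_genome(t, [contig], 0.92)
        assert matches
        m = matches[0]
        assert len(m.blocks) == 2
        (c1s, c1e, t1s, t1e), (c2s, c2e, t2s, t2e) = m.blocks
        assert t1e == t2s  # transcript ranges abut
        assert (t1s, t2e) == (0, 750)  # full transcript covered
        # the exon/intron boundary can shift by a few chance-matching
        # bases, but the intron span must be preserved
        assert abs((c2s - c1e) - 300) <= 8
        assert c1s == 500 and c2e == 1550
        assert m.identity >= 0.99

    def test_below_threshold_no_match(self):
        rng = _rng(3)
        contig = SeqRecord("c", random_sequence(rng, 2000))
        # ~80% identical to the best contig region
        t = SeqRecord("t", mutate_k80(contig.sequence[200:900], 0.25, 2.0, rng))
        assert match_transcript_to_genome(t, [contig], 0.92) == []

    def test_empty_contig_set(self):
        t = SeqRecord("t", "ACGT" * 50)
        assert match_transcript_to_genome(t, [], 0.9) == []

    def test_reverse_complement_reported_on_minus_strand(self):
        rng = _rng(4)
        contig = SeqRecord("c", random_sequence(rng, 2000))
        t = SeqRecord("t", revcomp(contig.sequence[300:800]))
        matches = match_transcript_to_genome(t, [contig], 0.95)
        assert len(matches) == 1
        m = matches[0]
        assert m.strand == "-"
        assert m.blocks[0][:2] == (300, 800)  # forward-contig coordinates
        assert m.identity == 1.0

    def test_identity_agrees_with_alignment_oracle(self):
        # ungapped divergence: the exhaustive oracle is the Hamming
        # identity of the planted placement
        rng = _rng(5)
        contig_seq = random_sequence(rng, 2500)
        region = contig_seq[400:1400]
        t = SeqRecord("t", mutate_k80(region, 0.05, 2.0, rng))
        oracle = sum(a == b for a, b in zip(t.sequence, region)) / 1000
        matches = match_transcript_to_genome(
            t, [SeqRecord("c", contig_seq)], 0.8)
        assert matches
        assert len(matches[0].blocks) == 1
        assert abs(matches[0].identity - oracle) <= 0.01


class TestGeneModel:
    def test_single_block(self):
        from baitforge.locus_selection import SplicedMatch
        m = SplicedMatch("t", "c", "+", [(100, 600, 0, 500)], 1.0)
        gm = infer_gene_model(m, "g", "K_africana")
        assert (gm.exon_count, gm.intron_count, gm.exonic_length) == (1, 0, 500)

    def test_three_blocks(self):
        from baitforge.locus_selection import SplicedMatch
        m = SplicedMatch("t", "c", "+",
                         [(0, 100, 0, 100), (200, 400, 100, 300),
                          (500, 800, 300, 600)], 1.0)
        gm = infer_gene_model(m, "g", "x")
        assert (gm.exon_count, gm.exonic_length) == (3, 600)

    def test_planted_eleven_exon_gene(self):
        from baitforge.synthetic_data import (SimulationSpec,
                                              simulate_reference_set)
        spec = SimulationSpec(seed=9, n_genes=1, n_contigs=1,
                              contig_length=30_000,
                              exon_count_range=(11, 11),
                              taxon_divergence={"T_umbellata": 0.0})
        contigs, trans, truth = simulate_reference_set(spec)
        assert truth.iloc[0]["intron_count"] == 10
        matches = match_transcript_to_genome(
            trans["T_umbellata"][0], contigs, 0.95)
        gm = infer_gene_model(matches[0], "g", "T_umbellata")
        assert gm.exon_count == 11
        assert gm.intron_count == 10


class TestCandidateFilter:
    CFG = RunConfig()

    def test_passing_gene_kept(self):
        m = GeneModel("g", "c", exon_count=10, exonic_length=1800)
        kept, rejected = filter_candidate_genes([m], self.CFG)
        assert kept == [m] and rejected == []

    def test_ten_introns_rejected(self):
        m = GeneModel("g", "c", exon_count=11, exonic_length=500)
        _, rejected = filter_candidate_genes([m], self.CFG)
        assert rejected == [(m, "introns")]

    def test_exact_length_cap_rejected(self):
        m = GeneModel("g", "c", exon_count=1, exonic_length=2040)
        _, rejected = filter_candidate_genes([m], self.CFG)
        assert rejected == [(m, "length")]

    def test_filter_order_invariance(self):
        rng = _rng(6)
        models = [
            GeneModel(f"g{i}", "c",
                      exon_count=int(rng.integers(1, 15)),
                      exonic_length=int(rng.integers(100, 3000)))
            for i in range(200)
        ]
        kept, _ = filter_candidate_genes(models, self.CFG)
        manual = [m for m in models
                  if m.exonic_length < 2040 and m.intron_count < 10]
        manual2 = [m for m in models
                   if m.intron_count < 10 and m.exonic_length < 2040]
        assert kept == manual == manual2


class TestClusterAndIntersect:
    def test_identical_gene_two_datasets_kept(self):
        seq = random_sequence(_rng(7), 800)
        recs = [SeqRecord("k1", seq, dataset="K"),
                SeqRecord("m1", seq, dataset="M")]
        clusters, kept = cluster_and_intersect(recs, 0.9)
        assert len(clusters) == 1
        assert len(kept) == 1
        assert kept[0].datasets == {"K", "M"}

    def test_singleton_dataset_dropped(self):
        recs = [SeqRecord("t1", random_sequence(_rng(8), 500), dataset="T")]
        clusters, kept = cluster_and_intersect(recs, 0.9)
        assert len(clusters) == 1 and kept == []

    def test_diverged_pair_below_threshold_two_singletons(self):
        # two genes at ~85% identity from different datasets; the oracle
        # is the global-alignment identity of the pair
        rng = _rng(9)
        a = random_sequence(rng, 1000)
        b = mutate_k80(a, 0.17, 2.0, rng)
        assert 0.82 < pair_identity(a, b) < 0.88
        clusters, kept = cluster_and_intersect(
            [SeqRecord("a", a, dataset="K"), SeqRecord("b", b, dataset="M")],
            0.9)
        assert len(clusters) == 2 and kept == []

    def test_recovers_planted_shared_set(self):
        # genes shared by >=2 datasets separated by pairwise divergence
        # 0.05 cluster together at threshold 0.9; singletons do not
        rng = _rng(10)
        recs = []
        shared = set()
        for g in range(20):
            base = random_sequence(rng, 900)
            n_datasets = 1 + (g % 3)  # 1, 2 or 3 datasets
            if n_datasets >= 2:
                shared.add(f"g{g}")
            for d in range(n_datasets):
                recs.append(SeqRecord(
                    f"g{g}", mutate_k80(base, 0.025, 2.0, rng),
                    dataset=f"ds{d}"))
        _, kept = cluster_and_intersect(recs, 0.9)
        recovered = {cl.representative.id for cl in kept}
        assert recovered == shared


class TestPanelReferences:
    def _aln(self, rows):
        return Alignment([t for t, _ in rows], [r for _, r in rows])

    def test_longest_family_row_wins(self):
        aln = self._aln([("famA", "ACGT" * 75 + "-" * 200),
                         ("famB", "ACGT" * 125),
                         ("out1", "ACGT" * 125)])
        refs, unresolved = select_panel_references(
            {"L1": aln}, {"famA", "famB"}, ["out1"])
        assert unresolved == []
        assert refs["L1"].dataset == "famB"
        assert len(refs["L1"].sequence) == 500

    def test_fallback_outgroup_used(self):
        aln = self._aln([("out1", "ACGTACGT"), ("out2", "ACGTACGA")])
        refs, _ = select_panel_references({"L1": aln}, {"famA"},
                                          ["out2", "out1"])
        assert refs["L1"].dataset == "out2"

    def test_tie_broken_lexicographically(self):
        aln = self._aln([("famB", "ACGTACGT"), ("famA", "TTTTTTTT")])
        refs, _ = select_panel_references({"L1": aln}, {"famA", "famB"}, [])
        assert refs["L1"].dataset == "famA"

    def test_unresolvable_locus_reported(self):
        aln = self._aln([("x", "ACGT")])
        refs, unresolved = select_panel_references({"L1": aln}, {"fam"},
                                                   ["y"])
        assert refs == {} and unresolved == ["L1"]

    def test_reference_is_degapped(self):
        aln = self._aln([("famA", "AC--GT--")])
        refs, _ = select_panel_references({"L1": aln}, {"famA"}, [])
        assert refs["L1"].sequence == "ACGT"


class TestCopyNumber:
    def test_planted_once(self):
        rng = _rng(11)
        contig = SeqRecord("c", random_sequence(rng, 4000))
        ref = SeqRecord("r", contig.sequence[1000:1800])
        assert copy_number_check(ref, [contig], 0.9) == 1

    def test_planted_twice_different_contigs(self):
        rng = _rng(12)
        gene = random_sequence(rng, 700)
        c1 = SeqRecord("c1", random_sequence(rng, 500) + gene
                       + random_sequence(rng, 500))
        copy2 = mutate_k80(gene, 0.03, 2.0, rng)
        c2 = SeqRecord("c2", random_sequence(rng, 300) + copy2
                       + random_sequence(rng, 300))
        assert copy_number_check(SeqRecord("r", gene), [c1, c2], 0.9) == 2

    def test_no_match_zero(self):
        rng = _rng(13)
        contig = SeqRecord("c", random_sequence(rng, 2000))
        ref = SeqRecord("r", random_sequence(_rng(99), 600))
        assert copy_number_check(ref, [contig], 0.9) == 0

    def test_self_extracted_reference_at_least_one(self, reference_set,
                                                   planted_references):
        contigs, _, _ = reference_set
        for locus in planted_references[:4]:
            assert copy_number_check(locus.reference, contigs, 0.9) >= 1


class TestDedupePanels:
    def _locus(self, gid, panel, seq):
        return TargetLocus(gid, panel, [SeqRecord(gid, seq)])

    def test_shared_gene_keeps_angio353(self):
        seq = random_sequence(_rng(14), 600)
        merged = dedupe_panels({
            "angio353": [self._locus("gA", "angio353", seq)],
            "functional": [self._locus("gF", "functional", seq)],
        }, 0.9)
        assert [(l.gene_id, l.panel) for l in merged] == [("gA", "angio353")]

    def test_disjoint_panels_concatenated_in_order(self):
        rng = _rng(15)
        a = self._locus("a", "angio353", random_sequence(rng, 500))
        f = self._locus("f", "functional", random_sequence(rng, 500))
        c = self._locus("c", "custom", random_sequence(rng, 500))
        merged = dedupe_panels(
            {"custom": [c], "angio353": [a], "functional": [f]}, 0.9)
        assert [l.gene_id for l in merged] == ["a", "f", "c"]

    def test_three_way_duplicate_single_survivor(self):
        rng = _rng(16)
        seq = random_sequence(rng, 800)
        panels = {
            "angio353": [self._locus("a", "angio353",
                                     mutate_k80(seq, 0.01, 2.0, rng))],
            "functional": [self._locus("f", "functional",
                                       mutate_k80(seq, 0.01, 2.0, rng))],
            "custom": [self._locus("c", "custom",
                                   mutate_k80(seq, 0.01, 2.0, rng))],
        }
        merged = dedupe_panels(panels, 0.9)
        assert [(l.gene_id, l.panel) for l in merged] == [("a", "angio353")]
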