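"""Promoter windows, hit assignment, clustering, and the A-D groups."""

import numpy as np
import pytest

from cpxscreen.promoters import (
    GeneModel,
    assign_hits,
    build_clusters,
    build_promoter_windows,
    classify,
    distinct_boxes,
    rank_boxes,
    read_genes_gff3,
)
from cpxscreen.scan import ScanHit

CONTIG = {"chr": 10_000}


def hit(start, score=10.0, length=15, strand="+", contig="chr"):
    return ScanHit(contig, start, length, strand, score,
                   "GTAAACTGACGTAAAG"[:length])


class TestPromoterWindows:
    def test_plus_strand_arithmetic(self):
        w, = build_promoter_windows(
            [GeneModel("g", "chr", "+", 1000)], CONTIG)
        assert (w.start, w.end, w.clipped) == (300, 1100, False)

    def test_minus_strand_mirror_image(self):
        # mirror of the plus-strand window: 700 bp upstream (rightward) and
        # 100 bp downstream including the start-codon base itself
        w, = build_promoter_windows(
            [GeneModel("g", "chr", "-", 1000)], CONTIG)
        assert (w.start, w.end) == (901, 1701)
        assert w.width == 800

    def test_clipped_at_contig_start(self):
        w, = build_promoter_windows([GeneModel("g", "chr", "+", 50)], CONTIG)
        assert (w.start, w.end, w.clipped) == (0, 150, True)

    def test_start_codon_outside_contig_rejected(self):
        with pytest.raises(ValueError, match="outside contig"):
            build_promoter_windows([GeneModel("g", "chr", "+", 20_000)], CONTIG)

    def test_involution_under_genome_flip(self):
        """Windows recomputed on the reverse-complemented genome and mapped
        back are identical."""
        L = CONTIG["chr"]
        genes = [GeneModel("a", "chr", "+", 1000), GeneModel("b", "chr", "-", 4000)]
        flipped = [GeneModel(g.gene_id, "chr", "-" if g.strand == "+" else "+",
                             L - 1 - g.start_codon) for g in genes]
        original = build_promoter_windows(genes, CONTIG)
        mirrored = build_promoter_windows(flipped, CONTIG)
        for w, m in zip(original, mirrored):
            assert (w.start, w.end) == (L - m.end, L - m.start)


class TestAssignment:
    WINDOWS = [GeneModel("g", "chr", "+", 1000)]

    def _windows(self):
        return build_promoter_windows(self.WINDOWS, CONTIG)

    def test_full_containment_assigned(self):
        assigned = assign_hits([hit(310)], self._windows())
        assert [h.start for h in assigned["g"]] == [310]

    def test_partial_overlap_not_assigned(self):
        assert assign_hits([hit(295)], self._windows()) == {}

    def test_shared_hit_assigned_to_both_divergent_genes(self):
        genes = [GeneModel("left", "chr", "-", 2000),
                 GeneModel("right", "chr", "+", 2500)]
        windows = build_promoter_windows(genes, CONTIG)
        assigned = assign_hits([hit(2200)], windows)
        assert set(assigned) == {"left", "right"}

    def test_matches_bruteforce_double_loop(self, random_genome):
        rng = np.random.default_rng(17)
        genes = [GeneModel(f"g{i}", "chr", rng.choice(["+", "-"]),
                           int(rng.integers(800, 9_000)))
                 for i in range(40)]
        windows = build_promoter_windows(genes, CONTIG)
        hits = [hit(int(rng.integers(0, 9_900)), score=float(rng.normal()))
                for _ in range(300)]
        fast = assign_hits(hits, windows)
        brute = {}
        for h in hits:
            for w in windows:
                if w.start <= h.start and h.end <= w.end:
                    brute.setdefault(w.gene_id, []).append(h)
        assert set(fast) == set(brute)
        for gene in brute:
            assert sorted((h.start, h.strand) for h in fast[gene]) == \
                sorted((h.start, h.strand) for h in brute[gene])


class TestClusters:
    def test_short_gaps_merge(self):
        genes = [GeneModel("a", "chr", "+", 100, 200),
                 GeneModel("b", "chr", "+", 210, 300),
                 GeneModel("c", "chr", "+", 320, 400)]
        clusters = build_clusters(genes, max_gap=50)
        assert [c.gene_ids for c in clusters] == [("a", "b", "c")]

    def test_long_gap_splits(self):
        genes = [GeneModel("a", "chr", "+", 100, 200),
                 GeneModel("b", "chr", "+", 700, 800)]
        assert len(build_clusters(genes, max_gap=50)) == 2

    def test_strand_switch_always_splits(self):
        genes = [GeneModel("a", "chr", "+", 100, 200),
                 GeneModel("b", "chr", "-", 210, 205),
                 GeneModel("c", "chr", "+", 220, 300)]
        clusters = build_clusters(genes, max_gap=1_000)
        assert all(len(c) == 1 for c in clusters)


class TestClassification:
    def _fixture(self):
        """One exemplar of each layout on a toy contig."""
        genes = [
            # A: two-gene operon, two boxes in the lead gene's window
            GeneModel("opA1", "chr", "+", 1000, 1600),
            GeneModel("opA2", "chr", "+", 1630, 2200),
            # B: lone gene, two boxes in its window
            GeneModel("lonB", "chr", "+", 4000, 4600),
            # C: divergent pair sharing one intergenic box
            GeneModel("divL", "chr", "-", 6000, 5400),
            GeneModel("divR", "chr", "+", 6400, 7000),
            # D: lone gene, one box
            GeneModel("lonD", "chr", "+", 9000, 9600),
        ]
        hits = [hit(450), hit(700, score=12.0),       # -> opA1
                hit(3400), hit(3700, score=11.0),     # -> lonB
                hit(6180),                            # -> divL and divR
                hit(8500)]                            # -> lonD
        windows = build_promoter_windows(genes, CONTIG)
        return genes, windows, assign_hits(hits, windows)

    def test_each_layout_gets_its_group(self):
        genes, windows, assigned = self._fixture()
        cands = {c.gene_id: c for c in classify(assigned, genes, windows=windows)}
        assert cands["opA1"].group == "A"
        assert cands["lonB"].group == "B"
        assert cands["divL"].group == "C" and cands["divR"].group == "C"
        assert cands["lonD"].group == "D"

    def test_divergent_pair_cross_references(self):
        genes, windows, assigned = self._fixture()
        cands = {c.gene_id: c for c in classify(assigned, genes, windows=windows)}
        assert cands["divL"].shared_with == "divR"
        assert cands["divR"].shared_with == "divL"

    def test_exactly_one_group_per_candidate_and_box_multiplicity(self):
        genes, windows, assigned = self._fixture()
        cands = classify(assigned, genes, windows=windows)
        assert len(cands) == len({c.gene_id for c in cands})
        for c in cands:
            assert c.group in "ABCD"
            if c.group in "CD":
                assert len(c.boxes) == 1
            if c.group == "B":
                assert len(c.boxes) >= 2
            assert all(c.best_box.score >= b.score for b in c.boxes)

    def test_single_contained_box_is_group_d(self):
        genes = [GeneModel("g", "chr", "+", 1000, 1600)]
        windows = build_promoter_windows(genes, CONTIG)
        cands = classify(assign_hits([hit(500)], windows), genes, windows=windows)
        assert [(c.gene_id, c.group) for c in cands] == [("g", "D")]

    def test_zero_box_genes_absent(self):
        genes = [GeneModel("g", "chr", "+", 1000, 1600),
                 GeneModel("h", "chr", "+", 5000, 5600)]
        windows = build_promoter_windows(genes, CONTIG)
        cands = classify(assign_hits([hit(500)], windows), genes, windows=windows)
        assert [c.gene_id for c in cands] == ["g"]


class TestBoxRanking:
    def test_score_descending(self):
        boxes = [hit(100, score=12.3), hit(400, score=17.1)]
        assert [b.score for b in rank_boxes(boxes)] == [17.1, 12.3]

    def test_tie_breaks_by_coordinate(self):
        boxes = [hit(400, score=10.0), hit(100, score=10.0)]
        assert [b.start for b in rank_boxes(boxes)] == [100, 400]

    def test_operon_lead_box_ranks_first(self):
        # carA-carB-like layout: the box in front of the operon (CB1)
        # scores higher and must rank first
        cb1, cb2 = hit(200, score=16.2), hit(520, score=12.9)
        assert rank_boxes([cb2, cb1])[0] is cb1

    def test_overlapping_hits_collapse_to_best(self):
        a = hit(100, score=9.0)
        b = hit(101, score=11.0, length=16)
        boxes = distinct_boxes([a, b])
        assert len(boxes) == 1 and boxes[0] is b


def test_read_genes_gff3(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr\tsrc\tCDS\t1001\t1600\t.\t+\t0\tID=fwd\n"
        "chr\tsrc\tCDS\t2001\t2600\t.\t-\t0\tID=rev\n"
    )
    genes = {g.gene_id: g for g in read_genes_gff3(gff)}
    assert genes["fwd"].start_codon == 1000  # first CDS base, 0-based
    assert genes["rev"].start_codon == 2599  # rightmost base for minus strand
    assert genes["rev"].strand == "-"
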