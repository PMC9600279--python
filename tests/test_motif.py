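"""Motif model: counts, PWM, log-odds scoring, and the spacer-expansion rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpxscreen.motif import (
    ALPHABET,
    BackgroundModel,
    BindingSiteCollection,
    ScoringMatrix,
    build_count_matrix,
    build_matrix_from_sites,
    build_pssm,
    build_pwm,
    consensus,
    expand_collection,
    expand_spacer,
    read_matrix,
    read_sites,
    score_window,
    write_matrix,
)

dna = st.text(alphabet="ACGT", min_size=15, max_size=15)


class TestCountMatrix:
    def test_direct_tally(self):
        counts = build_count_matrix(BindingSiteCollection.from_sequences(["AC", "AG"]))
        assert counts.n_sites == 2
        assert counts.counts[0].tolist() == [2, 0, 0, 0]
        assert counts.counts[1].tolist() == [0, 1, 1, 0]

    def test_identical_sites(self):
        counts = build_count_matrix(
            BindingSiteCollection.from_sequences(["GTAAA"] * 3))
        assert (counts.counts.max(axis=1) == 3).all()
        assert (counts.counts.sum(axis=1) == 3).all()

    def test_columns_sum_to_collection_size(self):
        from cpxscreen.simulate import MotifSpec, sample_sites

        sites = sample_sites(MotifSpec(identity_prob=0.9), 41, seed=11)
        counts = build_count_matrix(sites)
        assert (counts.counts.sum(axis=1) == 41).all()

    @pytest.mark.parametrize("bad", [[], ["ACGT", "ACG"], ["ACNT"]])
    def test_invalid_collections_rejected(self, bad):
        with pytest.raises(ValueError):
            BindingSiteCollection.from_sequences(bad)


class TestSpacerExpansion:
    def test_middle_base_duplicated(self):
        assert expand_spacer("GTAAACCGCCGTAAA") == "GTAAACCGGCCGTAAA"

    def test_uniform_sequence_fixed_point(self):
        assert expand_spacer("A" * 15) == "A" * 16

    @given(dna)
    def test_duplicate_is_at_center_and_removable(self, site):
        out = expand_spacer(site)
        assert len(out) == 16
        assert out[7] == out[8] == site[7]
        assert out[:8] + out[9:] == site == out[:7] + out[8:]

    @pytest.mark.parametrize("bad", ["ACGT", "N" * 15, "A" * 16])
    def test_rejects_wrong_input(self, bad):
        with pytest.raises(ValueError):
            expand_spacer(bad)

    def test_expanded_collection_duplicates_column(self, toy_sites):
        c15 = build_count_matrix(toy_sites).counts
        c16 = build_count_matrix(expand_collection(toy_sites)).counts
        assert (c16[:8] == c15[:8]).all()
        assert (c16[8] == c15[7]).all()
        assert (c16[9:] == c15[8:]).all()


class TestPwm:
    def test_single_site_pseudocount(self):
        counts = build_count_matrix(BindingSiteCollection.from_sequences(["G"]))
        p = build_pwm(counts, 0.5).probabilities[0]
        assert p[ALPHABET.index("G")] == pytest.approx(1.5 / 3)
        assert p[ALPHABET.index("A")] == pytest.approx(0.5 / 3)

    def test_maximum_likelihood_limit(self):
        counts = build_count_matrix(BindingSiteCollection.from_sequences(["A"] * 4))
        p = build_pwm(counts, 0.0).probabilities[0]
        assert p.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_formula_41_sites(self):
        # column counts (20, 10, 5, 6) over 41 sites, beta = 0.5
        sites = ["A"] * 20 + ["C"] * 10 + ["G"] * 5 + ["T"] * 6
        counts = build_count_matrix(BindingSiteCollection.from_sequences(sites))
        p = build_pwm(counts, 0.5).probabilities[0]
        assert p[0] == pytest.approx(20.5 / 43, abs=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_pseudocount_rejected(self):
        counts = build_count_matrix(BindingSiteCollection.from_sequences(["A"]))
        with pytest.raises(ValueError):
            build_pwm(counts, -0.1)

    def test_pseudocount_pulls_towards_uniform(self):
        counts = build_count_matrix(BindingSiteCollection.from_sequences(["A"] * 8))
        prev = None
        for beta in (0.5, 2.0, 50.0, 5000.0):
            p = build_pwm(counts, beta).probabilities[0]
            dev = float(np.abs(p - 0.25).max())
            if prev is not None:
                assert dev < prev
            prev = dev
        assert prev < 1e-3  # beta -> infinity limit is uniform


class TestPssm:
    def test_uniform_pwm_scores_zero(self):
        counts = build_count_matrix(
            BindingSiteCollection.from_sequences(["A", "C", "G", "T"]))
        matrix = build_pssm(build_pwm(counts, 0.0))
        assert np.allclose(matrix.scores, 0.0)

    def test_one_bit_doubling(self):
        # p = 0.5 against q = 0.25 is exactly one bit
        counts = build_count_matrix(BindingSiteCollection.from_sequences(["G"]))
        matrix = build_pssm(build_pwm(counts, 0.5))
        assert matrix.scores[0, ALPHABET.index("G")] == pytest.approx(1.0)

    def test_zero_probability_rejected(self):
        counts = build_count_matrix(BindingSiteCollection.from_sequences(["A"]))
        with pytest.raises(ValueError, match="pseudocount"):
            build_pssm(build_pwm(counts, 0.0))

    def test_matches_hand_computed_log_odds(self, toy_sites):
        """Independent oracle: apply the two formulas cell by cell."""
        matrix = build_matrix_from_sites(toy_sites, 0.5)
        raw = [list(s) for s in toy_sites.sites]
        for pos in range(15):
            for bi, base in enumerate(ALPHABET):
                n = sum(1 for site in raw if site[pos] == base)
                expected = math.log2(((n + 0.5) / (4 + 2.0)) / 0.25)
                assert matrix.scores[pos, bi] == pytest.approx(expected, abs=1e-12)

    def test_round_trip_recovers_probability_ratio(self, toy_sites):
        counts = build_count_matrix(toy_sites)
        pwm = build_pwm(counts, 0.5)
        matrix = build_pssm(pwm)
        ratio = 2.0 ** np.asarray(matrix.scores)
        assert np.allclose(ratio * 0.25, pwm.probabilities, atol=1e-9)

    def test_matches_biopython_reference(self, toy_sites):
        """Cross-check against the independent Bio.motifs implementation."""
        from Bio import motifs
        from Bio.Seq import Seq

        m = motifs.create([Seq(s) for s in toy_sites.sites])
        ref_pwm = m.counts.normalize(pseudocounts=0.5)
        ref_pssm = ref_pwm.log_odds()
        mine = build_matrix_from_sites(toy_sites, 0.5)
        for pos in range(15):
            for bi, base in enumerate(ALPHABET):
                assert mine.scores[pos, bi] == pytest.approx(
                    ref_pssm[base][pos], abs=1e-9)


class TestScoreWindow:
    def test_consensus_achieves_maximum(self, toy_sites, toy_matrix):
        pwm = build_pwm(build_count_matrix(toy_sites), 0.5)
        assert score_window(toy_matrix, consensus(pwm)) == pytest.approx(
            toy_matrix.max_score)

    def test_zero_matrix_scores_zero(self):
        matrix = ScoringMatrix(np.zeros((15, 4)))
        assert score_window(matrix, "GTAAACTGACGTAAA") == 0.0

    def test_manual_cell_addition(self, toy_matrix):
        window = "GTAAACTGACGTAAA"
        expected = math.fsum(
            toy_matrix.scores[i, ALPHABET.index(b)] for i, b in enumerate(window))
        assert score_window(toy_matrix, window) == expected

    def test_length_mismatch_and_ambiguity_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            score_window(toy_matrix, "ACGT")
        with pytest.raises(ValueError):
            score_window(toy_matrix, "GTAAACTGACGTAAN")

    @given(dna)
    def test_reverse_complement_symmetry_bit_exact(self, window):
        from cpxscreen.motif import reverse_complement

        matrix = build_matrix_from_sites(BindingSiteCollection.from_sequences([
            "GTAAACTGACGTAAA", "GTAAAGGCTAGTAAA", "GTTAACTGACGTAAC",
        ]))
        forward = score_window(matrix, window)
        mirrored = score_window(matrix.reverse_complement(),
                                reverse_complement(window))
        assert forward == mirrored  # exactly rounded sums, order-independent


class TestConsensus:
    def test_flanks_of_bipartite_motif(self):
        from cpxscreen.simulate import MotifSpec, sample_sites

        sites = sample_sites(MotifSpec(identity_prob=1.0), 41, seed=5)
        pwm = build_pwm(build_count_matrix(sites), 0.5)
        cons = consensus(pwm)
        assert cons.startswith("GTAAA") and cons.endswith("GTAAA")

    def test_single_site_is_its_own_consensus(self):
        site = "GTAAACTGACGTAAA"
        pwm = build_pwm(build_count_matrix(
            BindingSiteCollection.from_sequences([site])), 0.5)
        assert consensus(pwm) == site

    def test_tie_breaks_in_fixed_base_order(self):
        pwm = build_pwm(build_count_matrix(
            BindingSiteCollection.from_sequences(["A", "A", "C", "C"])), 0.5)
        assert consensus(pwm) == "A"


class TestMatrixIO:
    def test_tsv_round_trip(self, toy_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_matrix(toy_matrix, path, pseudocount=0.5)
        back = read_matrix(path)
        assert np.array_equal(back.scores, toy_matrix.scores)
        assert back.background.q == toy_matrix.background.q

    def test_read_sites_fasta_and_plain(self, tmp_path):
        fasta = tmp_path / "sites.fa"
        fasta.write_text(">s1\nGTAAACTGACGTAAA\n>s2\nGTAAAGGCTAGTAAA\n")
        plain = tmp_path / "sites.txt"
        plain.write_text("# two sites\nGTAAACTGACGTAAA\nGTAAAGGCTAGTAAA\n")
        assert read_sites(fasta).sites == read_sites(plain).sites
        assert read_sites(fasta).labels == ("s1", "s2")
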