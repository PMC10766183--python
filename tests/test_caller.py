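"""Split-read detection, classification, junction characterization, depth."""

import numpy as np
import pytest

from odira._seq import revcomp
from odira import caller, simulate
from odira.caller import (Category, InvertedJunction, LoopSide, Orientation,
                          binned_depth, call_junctions,
                          characterize_inverted_junction, classify_split_read,
                          dedupe_and_threshold, find_split_reads,
                          orient_relative_to_locus)
from odira.simulate import (Molecule, MoleculeSet, Subclone, build_genome,
                            make_inverted_linear, make_triplication,
                            simulate_population, simulate_reads)


def _fold_read(seq, iir, x=70, read_len=150):
    """A read crossing the inverted-linear fold with x bases of inverted flank."""
    return revcomp(seq[iir.r2 : iir.r2 + x]) + seq[iir.l1 : iir.l1 + read_len - x]


class TestFindSplitReads:
    def test_exact_substring_not_split(self, small_genome):
        seq = small_genome.sequence("chrR")
        assert find_split_reads([("r", seq[100:250])], small_genome.contigs) == []
        assert find_split_reads([("r", revcomp(seq[100:250]))],
                                small_genome.contigs) == []

    def test_fold_read_gives_opposite_strand_segments(self, small_genome):
        seq = small_genome.sequence("chrR")
        (iir,) = small_genome.truth["chrR"]
        srs = find_split_reads([("r", _fold_read(seq, iir))], small_genome.contigs)
        assert len(srs) == 1
        sr = srs[0]
        assert {sr.prefix.strand, sr.suffix.strand} == {"+", "-"}
        assert sr.homology == iir.arm_len

    def test_direct_seam_gives_same_strand_segments(self, small_genome):
        seq = small_genome.sequence("chrR")
        read = seq[1000:1075] + seq[3000:3075]    # tandem-duplication style seam
        srs = find_split_reads([("r", read)], small_genome.contigs)
        assert len(srs) == 1
        sr = srs[0]
        assert sr.prefix.strand == sr.suffix.strand

    def test_k_longer_than_read_raises(self, small_genome):
        with pytest.raises(ValueError):
            find_split_reads([("r", "ACGTACGT")], small_genome.contigs, k=20)


class TestClassification:
    def test_inverted_direct_and_telomere_categories(self, small_genome):
        seq = small_genome.sequence("chrR")
        (iir,) = small_genome.truth["chrR"]
        inv = _fold_read(seq, iir)
        direct = seq[1000:1075] + seq[3000:3075]
        telo_unit = "".join(["CCA", "CA", "CCCA"] * 10)
        de_novo = seq[500:575] + telo_unit[:75]
        srs = find_split_reads(
            [("inv", inv), ("dir", direct), ("telo", de_novo)],
            small_genome.contigs)
        cats = {sr.read_id: classify_split_read(sr) for sr in srs}
        assert cats["inv"] is Category.INVERTED
        assert cats["dir"] is Category.DIRECT
        assert cats["telo"] is Category.DE_NOVO_TELOMERE

    def test_translocation_to_annotated_telomere(self):
        g = build_genome(15, 4000, telomeric_ends=True)
        contig, seq = g.contigs[0]
        tel_len = len(seq) - 4000
        # join interior sequence onto the existing right telomere
        read = seq[1000:1075] + seq[-80:-5]
        srs = find_split_reads([("r", read)], g.contigs)
        if srs:  # telomere repeats may be multi-mapping; then prefix-only split
            cat = classify_split_read(
                srs[0], telomere_annotation=[(contig, len(seq) - 150, len(seq))])
            assert cat in (Category.TELOMERE_TRANSLOCATION,
                           Category.DE_NOVO_TELOMERE)

    def test_every_split_read_gets_exactly_one_category(self, small_genome, rng):
        seq = small_genome.sequence("chrR")
        reads = []
        for i in range(60):
            a, b = rng.integers(0, len(seq) - 80, size=2)
            left = seq[a : a + 75]
            right = seq[b : b + 75]
            if i % 3 == 0:
                right = revcomp(right)
            reads.append((f"r{i}", left + right))
        srs = find_split_reads(reads, small_genome.contigs)
        for sr in srs:
            cat = classify_split_read(sr)
            assert isinstance(cat, Category)
            assert sr.category is cat


class TestCharacterize:
    def test_worked_example_arm4_spacer61(self, small_genome):
        seq = small_genome.sequence("chrR")
        (iir,) = small_genome.truth["chrR"]
        for x in (30, 55, 80, 110):
            srs = find_split_reads([("r", _fold_read(seq, iir, x=x))],
                                   small_genome.contigs)
            (sr,) = srs
            classify_split_read(sr)
            j = characterize_inverted_junction(sr)
            assert (j.arm_len, j.spacer_len, j.loop_side) == (4, 61, LoopSide.LEFT)
            assert j.pos == iir.junction_pos

    def test_blunt_foldback_arm0_spacer0(self):
        g = build_genome(33, 3000)
        seq = g.sequence("chrR")
        p = 1500
        # ensure no chance homology at the blunt fold
        read = None
        for q in range(p, p + 50):
            cand = revcomp(seq[q : q + 70]) + seq[q : q + 80]
            srs = find_split_reads([("r", cand)], g.contigs)
            if srs and srs[0].homology == 0:
                read = srs[0]
                break
        assert read is not None
        classify_split_read(read)
        j = characterize_inverted_junction(read)
        assert (j.arm_len, j.spacer_len) == (0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_planted_arm_spacer_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        arm = int(rng.integers(3, 11))
        spacer = int(rng.integers(0, 120))
        g = build_genome(1000 + seed, 6000, [(arm, spacer, 2500)])
        (iir,) = g.truth["chrR"]
        il = make_inverted_linear(g, iir)
        reads = simulate_reads(MoleculeSet([(il, 1.0)]), 50, 150, 0.0,
                               seed=seed + 1)
        js = call_junctions(reads, g.contigs, min_support=2)
        match = [j for j in js
                 if (j.arm_len, j.spacer_len, j.loop_side) ==
                    (arm, spacer, LoopSide.LEFT)]
        assert len(match) == 1, (arm, spacer, [(j.arm_len, j.spacer_len) for j in js])

    def test_non_inverted_read_rejected(self, small_genome):
        seq = small_genome.sequence("chrR")
        read = seq[1000:1075] + seq[3000:3075]
        (sr,) = find_split_reads([("r", read)], small_genome.contigs)
        classify_split_read(sr)
        with pytest.raises(ValueError):
            characterize_inverted_junction(sr)


class TestDedupeThreshold:
    def _junction(self, pos=100):
        return InvertedJunction("c", pos, 4, 61, LoopSide.LEFT,
                                n_reads=1, n_unique_fragments=1)

    def test_single_read_removed(self):
        assert dedupe_and_threshold([(self._junction(), ("c", 5, "+"))]) == []

    def test_identical_fragment_signatures_count_once(self):
        records = [(self._junction(), ("c", 5, "+")),
                   (self._junction(), ("c", 5, "+"))]
        assert dedupe_and_threshold(records) == []

    def test_two_unique_fragments_retained(self):
        records = [(self._junction(), ("c", 5, "+")),
                   (self._junction(), ("c", 9, "+")),
                   (self._junction(), ("c", 9, "+"))]
        (j,) = dedupe_and_threshold(records)
        assert j.n_reads == 3 and j.n_unique_fragments == 2


class TestOrientation:
    def _j(self, pos, loop):
        return InvertedJunction("c", pos, 4, 61, loop, 2, 2)

    def test_productive_and_nonproductive_rules(self):
        F = 1000
        assert orient_relative_to_locus(self._j(770, LoopSide.LEFT), F) is Orientation.CJ
        assert orient_relative_to_locus(self._j(1300, LoopSide.RIGHT), F) is Orientation.TJ
        assert orient_relative_to_locus(self._j(770, LoopSide.RIGHT), F) is Orientation.NONPRODUCTIVE
        assert orient_relative_to_locus(self._j(1300, LoopSide.LEFT), F) is Orientation.NONPRODUCTIVE

    def test_other_contig_is_na(self):
        j = self._j(770, LoopSide.LEFT)
        assert orient_relative_to_locus(j, 1000, locus_contig="chrX") is Orientation.NA

    def test_triplication_shows_perfect_orientation_split(self, two_iir_genome):
        cj, tj = two_iir_genome.truth["chrR"]
        tri = make_triplication(two_iir_genome, cj, tj)
        reads = simulate_reads(MoleculeSet([(tri, 1.0)]), 60, 150, 0.0, seed=9)
        locus = (cj.r2 + tj.l1) // 2
        js = call_junctions(reads, two_iir_genome.contigs, min_support=2,
                            locus=locus)
        assert js
        for j in js:
            if j.pos < locus:
                assert j.orientation is Orientation.CJ
            else:
                assert j.orientation is Orientation.TJ


class TestUnrearranged:
    def test_error_free_unrearranged_genome_yields_no_junctions(self):
        g = build_genome(44, 20_000, [(4, 61, 5000), (6, 30, 12_000)])
        contig, seq = g.contigs[0]
        reads = simulate_reads(MoleculeSet([(Molecule("chr", seq), 1.0)]),
                               50, 150, 0.0, seed=2)
        assert call_junctions(reads, g.contigs, min_support=2) == []


class TestBinnedDepth:
    def test_uniform_single_copy_near_one(self):
        g = build_genome(55, 20_000)
        contig, seq = g.contigs[0]
        reads = simulate_reads(MoleculeSet([(Molecule("chr", seq), 1.0)]),
                               100, 150, 0.0, seed=3)
        depth = binned_depth(reads, g.contigs, bin_size=500)[contig]
        inner = depth[1:-1]               # edge bins lose read starts
        # ~435 read starts per 500 bp bin at 100x -> ~4.8% relative SD
        assert np.all(np.abs(inner - 1.0) < 4 * 0.048)
        assert abs(inner.mean() - 1.0) < 0.03

    def test_triplication_mixture_raises_amplified_bins(self):
        f = 0.4
        g = build_genome(66, 30_000, [(5, 50, 10_000), (6, 40, 20_000)])
        contig, seq = g.contigs[0]
        cj, tj = g.truth[contig]
        tri = make_triplication(g, cj, tj)
        reads, _ = simulate_population(
            g, [Subclone("wt", [Molecule("chr", seq)], 1 - f),
                Subclone("tri", [tri], f)],
            artifact_rate=0.0, seed=8, depth=80)
        depth = binned_depth(reads, g.contigs, bin_size=500)[contig]
        amp = depth[24:36].mean()         # bins inside the amplified segment
        outside = np.r_[depth[4:16], depth[46:56]].mean()
        assert abs(outside - 1.0) < 0.15
        assert abs(amp - (1 + 2 * f) / 1.0) < 0.25 * (1 + 2 * f)

    def test_no_reads_errors(self, small_genome):
        with pytest.raises(ValueError):
            binned_depth([], small_genome.contigs)
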