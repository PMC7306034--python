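"""Conserved-block finding and hybrid primer construction."""

import pytest

from ndokit.codehop import (
    ConservedBlock, DesignError, ProteinMSA, build_primer, column_conservation,
    consensus_clamp, design_primer_pairs, find_conserved_blocks,
)
from ndokit.seqcore import CapacityError, CodonUsage
from ndokit.synth import FamilySpec, gen_protein_family


def msa_of(*rows):
    return ProteinMSA.from_records([(f"s{i}", r) for i, r in enumerate(rows)])


class TestColumnConservation:
    def test_fully_conserved(self):
        assert column_conservation(msa_of("C", "C", "C", "C"), 0) == ("C", 1.0)

    def test_gaps_excluded_from_denominator(self):
        aa, frac = column_conservation(msa_of("C", "C", "C", "S", "-"), 0)
        assert (aa, frac) == ("C", 0.75)

    def test_tie_breaks_alphabetically(self):
        assert column_conservation(msa_of("A", "C"), 0) == ("A", 0.5)

    def test_all_gap_sentinel(self):
        assert column_conservation(msa_of("-", "-"), 0) == ("-", 0.0)


class TestFindConservedBlocks:
    def test_fixture_motifs_recovered(self, ndo_family):
        blocks = find_conserved_blocks(ndo_family)
        by_motif = {b.core_aa: b for b in blocks}
        assert by_motif["CGTC"].start_col == 50
        assert by_motif["CGTC"].core_degeneracy == 64
        assert by_motif["WRAY"].start_col == 296
        assert by_motif["WRAY"].core_degeneracy == 64

    def test_identical_rows_every_window_qualifies(self):
        msa = msa_of("MWNDW", "MWNDW")
        blocks = find_conserved_blocks(msa, core_len=3, max_degeneracy=4096)
        assert [b.start_col for b in blocks] == [0, 1, 2]
        assert all(b.per_column_conservation == (1.0,) * 3 for b in blocks)

    def test_threshold_edge_excludes_three_quarters(self):
        # middle column is 3/4 conserved: below the 0.8 floor
        msa = msa_of("WWW", "WWW", "WWW", "WCW")
        assert find_conserved_blocks(msa, core_len=3, min_conservation=0.8) == []
        assert len(find_conserved_blocks(msa, core_len=3,
                                         min_conservation=0.75)) == 1

    def test_degeneracy_cap_filters_blocks(self):
        msa = msa_of("LLLL", "LLLL")  # YTN x4 = 8^4
        assert find_conserved_blocks(msa, core_len=4, max_degeneracy=64) == []

    def test_monotone_in_conservation_threshold(self):
        fam = gen_protein_family(FamilySpec(
            n_seqs=10, length=60, motifs={20: "CGTC"},
            conservation=0.8, seed=11))
        counts = [len(find_conserved_blocks(fam, min_conservation=t,
                                            max_degeneracy=4096))
                  for t in (0.5, 0.7, 0.8, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)


USAGE = CodonUsage.from_codon_frequencies({
    "ATT": 10, "CTG": 10, "GTA": 10, "TGT": 10, "GCC": 10, "TGG": 10,
    "CGT": 10, "TAT": 10, "ATG": 10,
})


class TestConsensusClamp:
    def test_upstream_lookup(self):
        msa = msa_of("ILVCLACGTC", "ILVCLACGTC")
        block = ConservedBlock(6, "CGTC", (1.0,) * 4, 64)
        clamp = consensus_clamp(msa, block, "upstream", clamp_aa=6,
                                codon_usage=USAGE)
        assert clamp == "ATTCTGGTATGTCTGGCC"
        assert len(clamp) == 18

    def test_extension_truncates_junction_residue(self):
        # one extra upstream residue (V) contributes its first two nt
        msa = msa_of("MILVCLAVCGTC", "MILVCLAVCGTC")
        block = ConservedBlock(8, "CGTC", (1.0,) * 4, 64)
        clamp = consensus_clamp(msa, block, "upstream", clamp_aa=6,
                                codon_usage=USAGE, extend_nt=2)
        assert clamp == "ATTCTGGTATGTCTGGCC" + "GT"
        assert len(clamp) == 20

    def test_single_row_alignment(self):
        msa = msa_of("WMCGTC")
        block = ConservedBlock(2, "CGTC", (1.0,) * 4, 64)
        assert consensus_clamp(msa, block, "upstream", clamp_aa=2,
                               codon_usage=USAGE) == "TGGATG"

    def test_all_gap_flank_column_rejected(self):
        msa = msa_of("I-VCLACGTC", "I-VCLACGTC")
        block = ConservedBlock(6, "CGTC", (1.0,) * 4, 64)
        with pytest.raises(DesignError):
            consensus_clamp(msa, block, "upstream", clamp_aa=6,
                            codon_usage=USAGE)

    def test_insufficient_flank_names_block(self):
        msa = msa_of("WCGTC")
        block = ConservedBlock(1, "CGTC", (1.0,) * 4, 64)
        with pytest.raises(DesignError, match="CGTC"):
            consensus_clamp(msa, block, "upstream", clamp_aa=6,
                            codon_usage=USAGE)


class TestBuildPrimer:
    def test_forward_wobble_trim_halves_degeneracy(self):
        block = ConservedBlock(0, "CGTC", (1.0,) * 4, 64)
        primer = build_primer(block, "ATGATG", "forward", wobble_trim=True)
        assert str(primer).endswith("tgyggnacntg")
        assert primer.degeneracy == 32

    def test_reverse_untrimmed_core(self):
        block = ConservedBlock(0, "WRAY", (1.0,) * 4, 64)
        primer = build_primer(block, "TGTGCC", "reverse", wobble_trim=False)
        assert str(primer).endswith("rtangcnckcca")
        assert str(primer).startswith("GGCACA")  # rc of the clamp
        assert primer.degeneracy == 64

    def test_empty_clamp_single_codon_core(self):
        block = ConservedBlock(0, "W", (1.0,), 1)
        primer = build_primer(block, "", "forward")
        assert str(primer) == "tgg"
        assert primer.degeneracy == 1

    def test_degenerate_clamp_rejected(self):
        block = ConservedBlock(0, "W", (1.0,), 1)
        with pytest.raises(DesignError):
            build_primer(block, "ATN", "forward")

    def test_capacity_error_over_budget(self):
        block = ConservedBlock(0, "LLL", (1.0,) * 3, 512)
        with pytest.raises(CapacityError):
            build_primer(block, "ATG", "forward", wobble_trim=False,
                         max_degeneracy=64)


class TestDesignPrimerPairs:
    def test_fixture_yields_single_pair_in_band(self, ndo_family, ndo_pair):
        assert ndo_pair.forward_block.core_aa == "CGTC"
        assert ndo_pair.reverse_block.core_aa == "WRAY"
        assert 700 <= ndo_pair.expected_product_bp <= 800
        assert ndo_pair.forward.degeneracy == 32
        assert ndo_pair.reverse.degeneracy == 64
        # primers carry the printed core sequences
        assert ndo_pair.forward_core == "tgyggnacntg"
        assert ndo_pair.reverse_core == "rtangcnckcca"

    def test_single_block_yields_no_pairs(self):
        fam = gen_protein_family(FamilySpec(
            n_seqs=8, length=60, motifs={20: "CGTC"},
            conservation=0.5, seed=7))
        assert design_primer_pairs(fam) == []

    def test_blocks_too_close_filtered_by_product_range(self):
        fam = gen_protein_family(FamilySpec(
            n_seqs=8, length=80, motifs={20: "CGTC", 40: "WRAY"},
            conservation=0.5, seed=7))
        assert design_primer_pairs(fam, product_range=(700, 800)) == []
        assert len(design_primer_pairs(fam, product_range=(50, 800))) == 1

    def test_designed_core_expansions_translate_to_motif_prefix(self, ndo_pair):
        # frame-0 translation of the core's complete codons gives the
        # block's consensus residues at every expansion
        core = ndo_pair.forward_core
        from ndokit.seqcore import expand, translate
        n_full = len(core) - len(core) % 3
        proteins = {translate(e[:n_full]) for e in expand(core, cap=64)}
        assert proteins == {"CGT"}

    def test_all_designed_degeneracies_within_budget(self, ndo_family):
        for cap in (64, 128):
            for p in design_primer_pairs(ndo_family, max_degeneracy=cap,
                                         extend_nt=2):
                assert p.forward.degeneracy <= cap
                assert p.reverse.degeneracy <= cap
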