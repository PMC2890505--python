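"""ORF arithmetic, locus layout, cleavage, methylation rules, inverse PCR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtase_architect.alphabet_core import NucSeq, ProteinSeq, reverse_complement
from mtase_architect.primer_design import DegeneratePrimer, design_primer
from mtase_architect.rm_locus import (
    Gene,
    MethylationEvidence,
    NRUI,
    RMLocus,
    SBO13I,
    call_methylation_type,
    cleave,
    dam_sites,
    find_sites,
    locus_layout,
    orf_protein_length,
    read_gene_table,
    simulate_inverse_pcr,
    site_is_blocked,
    write_gene_table,
)


class TestOrfArithmetic:
    @pytest.mark.parametrize("bp,aa", [(804, 267), (660, 219), (6, 1)])
    def test_gene_sizes(self, bp, aa):
        assert orf_protein_length(bp) == aa

    def test_incomplete_orf_rejected(self):
        with pytest.raises(ValueError, match="not a complete ORF|not divisible"):
            orf_protein_length(805)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            orf_protein_length(3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 10_000))
    def test_inverse_of_three_n_plus_one(self, n):
        assert orf_protein_length(3 * (n + 1)) == n


class TestLocusLayout:
    def _dna(self, n):
        return NucSeq(id="L", residues="A" * n)

    def test_divergent_pair_with_326_gap(self):
        locus = RMLocus(
            sequence=self._dna(2000),
            genes=(
                Gene(name="nruIR", role="R", start=1, end=660, strand="-"),
                Gene(name="nruIM", role="M", start=987, end=1790, strand="+"),
            ),
        )
        (rep,) = locus_layout(locus)
        assert rep.gap_bp == 326 and rep.orientation == "divergent" and not rep.overlap

    def test_adjacent_same_strand_tandem(self):
        locus = RMLocus(
            sequence=self._dna(100),
            genes=(
                Gene(name="a", role="C", start=1, end=30, strand="+"),
                Gene(name="b", role="R", start=31, end=60, strand="+"),
            ),
        )
        (rep,) = locus_layout(locus)
        assert rep.orientation == "tandem" and rep.gap_bp == 0

    def test_three_gene_controller_layout(self):
        # controller and R tandem on one strand, M opposite
        locus = RMLocus(
            sequence=self._dna(3000),
            genes=(
                Gene(name="sbo13IC", role="C", start=1, end=240, strand="+"),
                Gene(name="sbo13IR", role="R", start=280, end=939, strand="+"),
                Gene(name="sbo13IM", role="M", start=1000, end=1803, strand="-"),
            ),
        )
        reps = locus_layout(locus)
        assert reps[0].orientation == "tandem"
        assert reps[1].orientation == "convergent"  # -> then <-

    def test_overlapping_genes_flagged(self):
        locus = RMLocus(
            sequence=self._dna(100),
            genes=(
                Gene(name="a", role="R", start=1, end=60, strand="+"),
                Gene(name="b", role="M", start=55, end=90, strand="+"),
            ),
        )
        (rep,) = locus_layout(locus)
        assert rep.overlap and rep.gap_bp == 0

    def test_gene_table_round_trip(self, tmp_path):
        genes = (
            Gene(name="r", role="R", start=10, end=69, strand="-"),
            Gene(name="m", role="M", start=100, end=201, strand="+"),
        )
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        assert read_gene_table(path) == genes


class TestSitesAndCleavage:
    def test_single_site_blunt_fragments(self):
        dna = NucSeq(id="d", residues="TTCGCGAA")
        assert find_sites(dna, NRUI) == [2]
        frags = cleave(dna, NRUI)
        assert [f.residues for f in frags] == ["TTCG", "CGAA"]
        assert NRUI.blunt and NRUI.overhang == 0

    def test_dam_methylation_blocks_nrui_but_not_sbo13i(self):
        dna = NucSeq(id="d", residues="AATCGCGATCAA")
        marks = dam_sites(dna)
        assert marks  # the GATC overlap is auto-marked
        assert site_is_blocked(dna, 3, NRUI, marks) is True
        assert site_is_blocked(dna, 3, SBO13I, marks) is False
        assert [f.residues for f in cleave(dna, NRUI, marks)] == [dna.residues]
        assert len(cleave(dna, SBO13I, marks)) == 2

    def test_unmethylated_overlap_cut_by_both(self):
        dna = NucSeq(id="d", residues="AATCGCGATCAA")
        assert len(cleave(dna, NRUI)) == 2
        assert len(cleave(dna, SBO13I)) == 2

    def test_palindrome_sites_mirror_on_reverse_complement(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300))
        seq = seq[:50] + "TCGCGA" + seq[56:150] + "TCGCGA" + seq[156:]
        dna = NucSeq(id="d", residues=seq)
        rc = reverse_complement(dna)
        n, k = len(seq), len(NRUI.recognition)
        mirrored = sorted(n - (p + k - 1) + 1 for p in find_sites(dna, NRUI))
        assert mirrored == find_sites(rc, NRUI)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fragments_concatenate_to_input(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 400))
        dna = NucSeq(id="d", residues=seq)
        frags = cleave(dna, NRUI)
        assert "".join(f.residues for f in frags) == seq

    def test_circular_digestion_conserves_bases(self):
        dna = NucSeq(id="d", residues="AAATCGCGATTTTCGCGAGG", topology="circular")
        frags = cleave(dna, NRUI)
        assert len(frags) == 2
        assert sorted("".join(f.residues for f in frags)) == sorted(dna.residues)


def _primer_from(seq: str, name: str) -> DegeneratePrimer:
    return DegeneratePrimer(
        seq=NucSeq(id=name, residues=seq), strand="sense", phospho5=False,
        source_peptide=ProteinSeq(id="na", residues="X"),
    )


class TestInversePCR:
    def _toy_genome(self):
        rng = np.random.default_rng(1)
        left = "".join(rng.choice(list("ACGT"), 60))
        mid = "".join(rng.choice(list("ACGT"), 40))
        right = "".join(rng.choice(list("ACGT"), 60))
        # both primers sit on the downstream fragment; after self-ligation the
        # forward primer extends through the fragment end, across the junction,
        # and back to the reverse primer (classic outward-facing inverse PCR)
        fwd_site = "ACGTACGTACGT"  # forward primer binds here, extends right
        rev_core = "TGCATGCATGCA"  # reverse primer matches this plus-strand text
        genome = left + "TCGCGA" + "TTTT" + rev_core + mid + fwd_site + "TTTT" + right
        assert genome.count("TCGCGA") == 1
        return NucSeq(id="g", residues=genome), fwd_site, rev_core

    def test_amplicon_crosses_ligation_junction(self):
        genome, fwd_site, rev_core = self._toy_genome()
        p_fwd = _primer_from(fwd_site, "fwd")
        p_rev = _primer_from(reverse_complement(rev_core), "rev")
        amps = simulate_inverse_pcr(genome, NRUI, (p_fwd, p_rev))
        crossing = [a for a in amps if a.crosses_junction]
        assert crossing, "expected an amplicon across the self-ligation junction"
        # string-surgery oracle: digesting by hand, the junction product is
        # suffix-from-fwd + prefix-to-rev-5' of the same fragment
        cut = genome.residues.index("TCGCGA") + 3
        frag = genome.residues[cut:]  # the right fragment self-ligates
        fwd_pos = frag.index(fwd_site)
        rev_end = frag.index(rev_core) + len(rev_core)
        expected = frag[fwd_pos:] + frag[:rev_end]
        assert any(a.sequence == expected for a in crossing)

    def test_relinearized_product_swaps_fragment_ends(self):
        genome, fwd_site, rev_core = self._toy_genome()
        p_fwd = _primer_from(fwd_site, "fwd")
        p_rev = _primer_from(reverse_complement(rev_core), "rev")
        amps = [a for a in simulate_inverse_pcr(genome, NRUI, (p_fwd, p_rev))
                if a.crosses_junction]
        cut = genome.residues.index("TCGCGA") + 3
        frag = genome.residues[cut:]
        a = amps[0]
        n = len(frag)
        junction_offset = n - (a.fwd_pos - 1)
        assert a.sequence[:junction_offset] == frag[a.fwd_pos - 1 :]
        assert a.sequence[junction_offset:] == frag[: a.rev_pos]

    def test_primers_on_different_fragments_give_nothing(self):
        rng = np.random.default_rng(2)
        left = "".join(rng.choice(list("ACGT"), 100))
        right = "".join(rng.choice(list("ACGT"), 100))
        genome = NucSeq(id="g", residues="AAACCCGGGTTT" + left + "TCGCGA" + right + "CATCATCAT")
        p1 = _primer_from("AAACCCGGGTTT", "p1")  # on the left fragment, plus strand
        p2 = _primer_from(reverse_complement("CATCATCAT"), "p2")  # right fragment, minus
        amps = simulate_inverse_pcr(genome, NRUI, (p1, p2))
        # each pairing needs both primers on one circle; here every circle has one
        assert amps == []

    def test_no_recognition_site_no_product(self):
        genome = NucSeq(id="g", residues="ACGT" * 50)
        p = _primer_from("ACGTACGT", "p")
        assert simulate_inverse_pcr(genome, NRUI, (p, p)) == []


class TestMethylationCall:
    def test_nrui_profile_is_n6ma(self):
        ev = MethylationEvidence(dotblot_n6ma="pos", dam_overlap_cleaved="no")
        call, rationale = call_methylation_type(ev)
        assert call == "N6mA" and len(rationale) == 2

    def test_sbo13i_profile_is_n4mc(self):
        ev = MethylationEvidence(
            dotblot_n4mc="pos", mrr_restricted="no", dam_overlap_cleaved="yes",
            homology_hint="N4mC",
        )
        call, rationale = call_methylation_type(ev)
        assert call == "N4mC" and len(rationale) == 4

    def test_tie_is_inconclusive(self):
        ev = MethylationEvidence(dotblot_n6ma="pos", dotblot_n4mc="pos")
        call, _ = call_methylation_type(ev)
        assert call == "inconclusive"

    def test_all_untested_rejected(self):
        with pytest.raises(ValueError, match="untested"):
            call_methylation_type(MethylationEvidence())

    def test_invalid_value_rejected(self):
        with pytest.raises(ValueError):
            MethylationEvidence(dotblot_n6ma="maybe")
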