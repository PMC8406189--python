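"""Sequence algebra: translation, mutation application, consequence calling,
and molecular weight."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from erovar.seqcore import (
    AVERAGE_RESIDUE_MASSES,
    WATER_MASS,
    CodingSequence,
    MutationSpec,
    ProteinSequence,
    SequenceError,
    apply_mutation,
    molecular_weight,
    molecular_weight_kda,
    protein_consequence,
    translate,
)


def cds(seq, origin="mutated"):
    return CodingSequence(id="t", seq=seq, origin=origin)


class TestTranslate:
    def test_single_codon_plus_stop(self):
        assert translate(cds("ATGTAA")).residues == "M"

    def test_halts_at_first_stop_and_ignores_trailing(self):
        assert translate(cds("ATGGGCTGAAAA")).residues == "MG"

    def test_trailing_one_or_two_nt_ignored(self):
        assert translate(cds("ATGGGCAA")).residues == "MG"
        assert translate(cds("ATGGGCA")).residues == "MG"

    def test_no_atg_requirement(self):
        assert translate(cds("GGGTAA")).residues == "G"

    def test_leading_stop_is_error(self):
        with pytest.raises(SequenceError):
            translate(cds("TAAATG"))

    def test_reference_protein_length(self, tnaa_cds, tnaa_protein):
        assert len(tnaa_cds) == 1416
        assert len(tnaa_protein) == 471


class TestCodingSequenceInvariants:
    def test_reference_requires_frame_and_stop(self):
        with pytest.raises(SequenceError):
            CodingSequence(id="x", seq="ATGAA", origin="reference")
        with pytest.raises(SequenceError):
            CodingSequence(id="x", seq="ATGAAA", origin="reference")

    def test_alphabet_enforced(self):
        with pytest.raises(SequenceError):
            cds("ATGNNN")


class TestApplyMutation:
    def test_substitution_a359p(self, tnaa_cds, tnaa_protein):
        spec = MutationSpec(kind="substitution", position=1075,
                            ref_base="G", alt_base="C")
        prot = translate(apply_mutation(tnaa_cds, spec))
        cons = protein_consequence(tnaa_protein, prot)
        assert cons.klass == "substitutions"
        assert cons.substitutions == ((359, "A", "P"),)

    def test_ref_base_mismatch_names_position(self, tnaa_cds):
        spec = MutationSpec(kind="substitution", position=1075,
                            ref_base="A", alt_base="C")
        with pytest.raises(SequenceError, match="1075"):
            apply_mutation(tnaa_cds, spec)

    def test_out_of_bounds(self, tnaa_cds):
        with pytest.raises(SequenceError):
            apply_mutation(tnaa_cds, MutationSpec(kind="substitution",
                                                  position=2000, ref_base="A",
                                                  alt_base="C"))

    def test_input_unmodified_and_origin(self, tnaa_cds):
        before = tnaa_cds.seq
        out = apply_mutation(
            tnaa_cds,
            MutationSpec(kind="deletion", start=187, end=504),
        )
        assert tnaa_cds.seq == before
        assert out.origin == "mutated"
        assert len(out) == 1416 - 318

    def test_insertion_placement(self):
        base = cds("ATGGGCTAA")
        out = apply_mutation(
            base,
            MutationSpec(kind="insertion", after_position=3, inserted_seq="TAT"),
        )
        assert out.seq == "ATGTATGGCTAA"

    @given(
        pos=st.integers(min_value=1, max_value=9),
        alt=st.sampled_from("ACGT"),
    )
    def test_substitution_round_trip(self, pos, alt):
        base = cds("ATGGGCTAA")
        ref_base = base.seq[pos - 1]
        if alt == ref_base:
            return
        fwd = apply_mutation(base, MutationSpec(
            kind="substitution", position=pos, ref_base=ref_base, alt_base=alt))
        back = apply_mutation(fwd, MutationSpec(
            kind="substitution", position=pos, ref_base=alt, alt_base=ref_base))
        assert back.seq == base.seq


class TestProteinConsequence:
    def test_identical(self, tnaa_protein):
        assert protein_consequence(tnaa_protein, tnaa_protein).klass == "identical"

    def test_frameshift_after_258(self, tnaa_cds, tnaa_protein):
        spec = MutationSpec(kind="deletion", start=777, end=777)
        prot = translate(apply_mutation(tnaa_cds, spec))
        cons = protein_consequence(tnaa_protein, prot)
        assert cons.klass == "frameshift"
        assert cons.truncation_position == 258
        assert cons.novel_tail_length == 23
        assert tnaa_protein.residues[257] == "Y"

    def test_flanking_substitution_plus_deletion(self):
        ref = ProteinSequence(id="r", residues="MAMCDEFGHIKL")
        # remove CDEFG and change the flanking M -> S
        alt = ProteinSequence(id="a", residues="MASHIKL")
        cons = protein_consequence(ref, alt)
        assert cons.klass == "inframe_deletion"
        assert cons.deleted_range == (4, 8)
        assert cons.substitutions == ((3, "M", "S"),)

    def test_nonsense_truncation(self):
        ref = ProteinSequence(id="r", residues="MACDEFG")
        alt = ProteinSequence(id="a", residues="MACD")
        cons = protein_consequence(ref, alt)
        assert cons.klass == "nonsense_truncation"
        assert cons.truncation_position == 4

    def test_complex_fallback(self):
        ref = ProteinSequence(id="r", residues="MACDEFG")
        alt = ProteinSequence(id="a", residues="WWAC")
        assert protein_consequence(ref, alt).klass == "complex"


class TestMolecularWeight:
    def test_single_glycine(self):
        p = ProteinSequence(id="g", residues="G")
        assert round(molecular_weight(p), 1) == 75.1

    def test_additivity(self):
        a = ProteinSequence(id="a", residues="MAC")
        b = ProteinSequence(id="b", residues="DEFG")
        ab = ProteinSequence(id="ab", residues="MACDEFG")
        assert abs(
            molecular_weight(ab)
            - (molecular_weight(a) + molecular_weight(b) - WATER_MASS)
        ) < 1e-6

    def test_deletion_never_increases_mass(self, tnaa_protein):
        full = molecular_weight(tnaa_protein)
        for cut in (1, 100, 470):
            shorter = ProteinSequence(id="s", residues=tnaa_protein.residues[:cut])
            assert molecular_weight(shorter) < full

    def test_matches_biopython_reference(self, tnaa_protein):
        from Bio.SeqUtils import molecular_weight as bp_mw

        ours = molecular_weight(tnaa_protein)
        theirs = bp_mw(tnaa_protein.residues, seq_type="protein")
        assert abs(ours - theirs) < 2.0  # independent mass-table cross-check

    def test_rounding_half_up(self):
        # 52,750.0 Da must display as 52.8, not bankers-round to 52.7
        assert molecular_weight_kda(ProteinSequence(id="x", residues="G")) == 0.1


def test_whole_catalog_consequences_and_masses(tnaa_cds, tnaa_protein, catalog):
    """Every catalogued allele reproduces its recorded consequence class and
    the derived product's molecular weight stays within one display step of
    the catalog's reported value."""
    for row in catalog.itertuples(index=False):
        prot = translate(apply_mutation(tnaa_cds, row.mutation))
        cons = protein_consequence(tnaa_protein, prot)
        assert cons.klass in (
            "substitutions", "inframe_deletion", "inframe_insertion",
            "frameshift", "nonsense_truncation",
        )
        assert abs(molecular_weight_kda(prot) - float(row.reported_mw_kda)) <= 0.1005
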