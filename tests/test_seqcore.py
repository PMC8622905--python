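"""Heptad register, fragment design, mutations, masses."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccmelt import fixtures, seqcore
from ccmelt.errors import (
    AlignmentError,
    AlphabetError,
    CoverageError,
    PositionError,
    ValidationError,
)
from ccmelt.seqcore import (
    IsoformSequence,
    apply_mutation,
    assign_heptad,
    count_heptads,
    design_fragment,
    diff_fragments,
    molecular_weight,
    wheel_report,
)


class TestAssignHeptad:
    @pytest.mark.parametrize(
        "position, letter",
        [(92, "a"), (95, "d"), (64, "a"), (91, "g"), (93, "b"), (154, "g")],
    )
    def test_register_from_core_anchor(self, tpm1_annotation, position, letter):
        assert tpm1_annotation.letter(position) == letter

    def test_tpm3_r91_is_outer_f(self, tpm3_region):
        ann = assign_heptad(tpm3_region, 93, "a")
        assert ann.letter(91) == "f"
        assert ann.surface_class(91) == "outer"

    def test_anchor_consistency(self, tpm1_region):
        a = assign_heptad(tpm1_region, 92, "a")
        d = assign_heptad(tpm1_region, 95, "d")
        assert a.letters == d.letters

    def test_absent_anchor_raises(self, tpm1_region):
        with pytest.raises(PositionError):
            assign_heptad(tpm1_region, 200, "a")
        with pytest.raises(ValidationError):
            assign_heptad(tpm1_region, 92, "h")

    @given(st.integers(min_value=64, max_value=147))
    def test_period_seven(self, position):
        ann = assign_heptad(fixtures.tpm1_region(), 92, "a")
        assert ann.letter(position) == ann.letter(position + 7)


class TestCountHeptads:
    def test_fragment_has_thirteen(self, tpm1_fragment, tpm1_annotation):
        assert count_heptads(tpm1_fragment, tpm1_annotation) == 13

    @pytest.mark.parametrize("length, expected", [(7, 1), (6, 0), (14, 2), (13, 1)])
    def test_small_fragments(self, length, expected):
        seq = IsoformSequence.from_string("x", "A" * length, 1)
        ann = assign_heptad(seq, 1, "a")
        frag = design_fragment(seq, 1, length, fusion_tag="")
        assert count_heptads(frag, ann) == expected

    def test_uncovered_fragment_raises(self, tpm1_fragment, tpm3_region):
        ann3 = assign_heptad(tpm3_region, 93, "a")
        with pytest.raises(CoverageError):
            count_heptads(tpm1_fragment, ann3)


class TestDesignFragment:
    def test_lengths_and_tag_numbering(self, tpm1_fragment):
        assert tpm1_fragment.tpm_length == 91
        assert len(tpm1_fragment.peptide_sequence) == 98
        assert tpm1_fragment.fusion_tag == "GSHMCGG"
        assert tpm1_fragment.tag_numbering == tuple(range(57, 64))
        assert tpm1_fragment.peptide_sequence.startswith("GSHMCGG")
        assert tpm1_fragment.residue_at(64) == "L"
        assert tpm1_fragment.residue_at(154) == "I"

    def test_degenerate_single_residue(self, tpm1_region):
        frag = design_fragment(tpm1_region, 92, 92, fusion_tag="")
        assert frag.peptide_sequence == "I"

    def test_out_of_range_raises(self, tpm1_region):
        with pytest.raises(PositionError):
            design_fragment(tpm1_region, 60, 154)


class TestApplyMutation:
    def test_r91c_lands_at_native_position(self, tpm3_fragment):
        mutant = apply_mutation(tpm3_fragment, fixtures.MUTATIONS["R91C"])
        assert mutant.residue_at(91) == "C"
        assert tpm3_fragment.residue_at(91) == "R"  # original unchanged

    def test_wt_mismatch_names_residues(self, tpm3_fragment):
        bad = seqcore.Mutation("Tpm3.12", 91, "K", "C")
        with pytest.raises(ValidationError, match="'K'.*'R'"):
            apply_mutation(tpm3_fragment, bad)

    def test_out_of_fragment_raises(self, tpm3_fragment):
        with pytest.raises(PositionError):
            apply_mutation(tpm3_fragment, seqcore.Mutation("Tpm3.12", 200, "R", "C"))

    @pytest.mark.parametrize("label", ["I92T", "V95A", "R91C", "R91P"])
    def test_reverse_mutation_roundtrip(self, tpm1_fragment, tpm3_fragment, label):
        m = fixtures.MUTATIONS[label]
        frag = tpm1_fragment if m.isoform_id == "Tpm1.1" else tpm3_fragment
        mutant = apply_mutation(frag, m)
        reverse = seqcore.Mutation(m.isoform_id, m.position, m.mut_aa, m.wt_aa)
        assert apply_mutation(mutant, reverse) == frag


class TestDiffFragments:
    def test_four_isoform_differences(self, tpm1_fragment, tpm3_fragment):
        diffs = diff_fragments(tpm1_fragment, tpm3_fragment, offset=1)
        assert [d[0] for d in diffs] == [79, 84, 132, 135]
        assert diffs[0] == (79, "T", 80, "A")
        assert diffs[-1] == (135, "Q", 136, "L")

    def test_identity_is_empty(self, tpm1_fragment):
        assert diff_fragments(tpm1_fragment, tpm1_fragment, 0) == []

    def test_single_point_mutant_diff(self, tpm3_fragment):
        mutant = apply_mutation(tpm3_fragment, fixtures.MUTATIONS["R91P"])
        diffs = diff_fragments(tpm3_fragment, mutant, 0)
        assert diffs == [(91, "R", 91, "P")]

    def test_symmetry_up_to_column_swap(self, tpm1_fragment, tpm3_fragment):
        fwd = diff_fragments(tpm1_fragment, tpm3_fragment, 1)
        rev = diff_fragments(tpm3_fragment, tpm1_fragment, -1)
        assert [(b, bb, a, aa) for a, aa, b, bb in fwd] == rev

    def test_length_mismatch_raises(self, tpm1_fragment, tpm1_region):
        short = design_fragment(tpm1_region, 64, 100)
        with pytest.raises(AlignmentError):
            diff_fragments(tpm1_fragment, short, 0)


class TestMolecularWeight:
    def test_glycine_free_amino_acid(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_fragment_monomer_near_11_kda(self, tpm1_fragment):
        assert molecular_weight(tpm1_fragment.peptide_sequence) == pytest.approx(
            11000, abs=500
        )

    def test_dimer_closure(self, tpm1_fragment):
        mono = molecular_weight(tpm1_fragment.peptide_sequence)
        dimer = molecular_weight(
            tpm1_fragment.peptide_sequence, "disulfide_dimer"
        )
        assert dimer - 2 * mono == pytest.approx(-2.016, abs=1e-9)
        assert dimer == pytest.approx(22000, abs=1000)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
           st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
    def test_appending_increases_mass(self, seq, extra):
        assert molecular_weight(seq + extra) > molecular_weight(seq)

    def test_unknown_residue_raises(self):
        with pytest.raises(AlphabetError):
            molecular_weight("GXG")


class TestWheelReport:
    def test_mutation_surface_classes(self, tpm1_annotation, tpm3_region):
        rep1 = wheel_report(
            tpm1_annotation,
            [fixtures.MUTATIONS["I92T"], fixtures.MUTATIONS["V95A"]],
        )
        assert list(rep1["surface_class"]) == ["core", "core"]
        assert list(rep1["heptad"]) == ["a", "d"]

        ann3 = assign_heptad(tpm3_region, 93, "a")
        rep3 = wheel_report(
            ann3, [fixtures.MUTATIONS["R91C"], fixtures.MUTATIONS["R91P"]]
        )
        assert list(rep3["surface_class"]) == ["outer", "outer"]

    def test_interface_positions(self, tpm1_annotation):
        # position 91 is g, position 96 is e: the electrostatic interface
        m91 = seqcore.Mutation("Tpm1.1", 91, "R", "A")
        m96 = seqcore.Mutation("Tpm1.1", 96, "E", "A")
        rep = wheel_report(tpm1_annotation, [m91, m96])
        assert list(rep["surface_class"]) == ["interface", "interface"]

    def test_unannotated_position_raises(self, tpm1_annotation):
        with pytest.raises(CoverageError):
            wheel_report(
                tpm1_annotation, [seqcore.Mutation("Tpm1.1", 300, "A", "G")]
            )
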