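"""Windowing, motif extraction and mutant register enumeration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neomotif.motif_core import (
    AMINO_ACIDS,
    Mutation,
    MutationVerificationError,
    PeptideWindow,
    ProteinRecord,
    SequenceError,
    apply_mutation,
    dedupe_mutations,
    enumerate_mutant_registers,
    extract_gem_i,
    extract_gem_ii,
    extract_tcem_i,
    extract_tcem_ii,
    mutant_relative_index,
    window_peptides,
)

clean_seq = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)
dirty_seq = st.text(alphabet=AMINO_ACIDS + "XUBZJO*", min_size=1, max_size=60)


class TestWindowing:
    def test_exact_width_yields_single_window(self):
        assert len(window_peptides(ProteinRecord("p", "ACDEFGHIK"), 9)) == 1

    def test_shorter_than_width_yields_none(self):
        assert window_peptides(ProteinRecord("p", "ACDEFGHI"), 9) == []

    def test_ambiguity_letter_removes_covering_windows(self):
        # X at position 6 disqualifies starts 1..6 of a 15-residue protein
        wins = window_peptides(ProteinRecord("p", "ACDEFXGHIKLMNPQ"), 9)
        assert [w.start for w in wins] == [7]

    def test_windows_match_protein_subsequence(self):
        protein = ProteinRecord("p", "ACDEFGHIKLMNPQR")
        for w in window_peptides(protein, 9):
            assert w.peptide == protein.sequence[w.start - 1 : w.start + 8]

    @given(seq=dirty_seq, width=st.sampled_from([9, 15]))
    @settings(max_examples=200, deadline=None)
    def test_count_matches_brute_force_scan(self, seq, width):
        protein = ProteinRecord("p", seq)
        expected = sum(
            all(c in AMINO_ACIDS for c in seq[s : s + width])
            for s in range(0, max(len(seq) - width + 1, 0))
        )
        assert len(window_peptides(protein, width)) == expected


class TestMotifExtraction:
    @pytest.mark.parametrize(
        "nine_mer,pentamer",
        [
            ("ACDEFGHIK", "EFGHI"),
            ("VGADGVGKS", "DGVGK"),  # KRAS G12D register absent from the proteome
            ("HMTEVVRHC", "EVVRH"),  # the one represented TP53 R175H register
        ],
    )
    def test_tcem_i_is_p4_to_p8(self, nine_mer, pentamer):
        assert extract_tcem_i(nine_mer).pentamer == pentamer

    def test_tcem_ii_discontinuous_positions(self):
        assert extract_tcem_ii("ACDEFGHIKLMNPQR").pentamer == "FGILM"
        assert extract_tcem_ii("A" * 15).pentamer == "AAAAA"

    @given(st.text(alphabet=AMINO_ACIDS, min_size=15, max_size=15))
    def test_tcem_ii_equals_core_9mer_selection(self, w):
        # independent double-index oracle: core 9mer starts at 15mer position 4
        core = w[3:12]
        expected = "".join(core[p - 1] for p in (2, 3, 5, 7, 8))
        assert extract_tcem_ii(w).pentamer == expected

    def test_gem_tetramers(self):
        assert extract_gem_i("ACDEFGHIK").tetramer == "ACDK"
        assert extract_gem_ii("ACDEFGHIKLMNPQR").tetramer == "EHKN"

    @given(st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=9))
    def test_gem_and_tcem_partition_the_9mer(self, w):
        combined = sorted(extract_gem_i(w).tetramer + extract_tcem_i(w).pentamer)
        assert combined == sorted(w)

    @given(
        w=st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=9),
        repl=st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=4),
    )
    def test_tcem_i_ignores_anchor_positions(self, w, repl):
        # permuting/replacing residues outside p4-p8 never changes the pentamer
        other = repl[0] + repl[1] + repl[2] + w[3:8] + repl[3]
        assert extract_tcem_i(other).pentamer == extract_tcem_i(w).pentamer

    def test_wrong_length_raises(self):
        with pytest.raises(SequenceError):
            extract_tcem_i("ACDEFGHIKL")
        with pytest.raises(SequenceError):
            extract_tcem_ii("ACDEFGHIK")


class TestMutation:
    def test_apply_substitutes_single_position(self):
        p = ProteinRecord("p", "ACDEF")
        m = Mutation("c", "p", 3, "D", "E")
        out = apply_mutation(p, m)
        assert out.sequence == "ACEEF" and out.is_mutant

    def test_ref_mismatch_raises_verification_error(self):
        with pytest.raises(MutationVerificationError) as err:
            apply_mutation(ProteinRecord("p", "ACDEF"), Mutation("c", "p", 3, "Y", "E"))
        assert err.value.protein_id == "p" and err.value.position == 3

    def test_apply_then_revert_is_identity(self):
        p = ProteinRecord("p", "ACDEFGHIK")
        m = Mutation("c", "p", 5, "F", "W")
        mut = apply_mutation(p, m)
        back = apply_mutation(
            ProteinRecord("p", mut.sequence), Mutation("c", "p", 5, "W", "F")
        )
        assert back.sequence == p.sequence

    def test_same_residue_change_is_rejected(self):
        with pytest.raises(SequenceError):
            Mutation("c", "p", 3, "D", "D")

    def test_dedupe_on_protein_position_alt(self):
        ms = [
            Mutation("c1", "p", 3, "D", "E"),
            Mutation("c2", "p", 3, "D", "E"),  # same change from another codon
            Mutation("c1", "p", 3, "D", "W"),
        ]
        assert len(dedupe_mutations(ms)) == 2


class TestRegisters:
    @pytest.fixture()
    def interior(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"  # length 40
        mut = Mutation("c", "p", 20, seq[19], "W" if seq[19] != "W" else "C")
        protein = apply_mutation(ProteinRecord("p", seq), mut)
        return protein, mut

    def test_interior_width9_has_9_registers_5_exposed(self, interior):
        protein, mut = interior
        regs = enumerate_mutant_registers(protein, mut, 9)
        assert len(regs) == 9
        assert sum(r.exposed for r in regs) == 5
        assert sorted(r.mutant_pocket for r in regs) == list(range(1, 10))

    def test_interior_width15_core_map(self, interior):
        protein, mut = interior
        regs = enumerate_mutant_registers(protein, mut, 15)
        assert len(regs) == 15
        assert sum(r.exposed for r in regs) == 5
        assert sum(r.mutant_pocket is None for r in regs) == 6
        in_core_gem = sum(
            r.mutant_pocket in (1, 4, 6, 9) for r in regs if r.mutant_pocket
        )
        assert in_core_gem == 4

    def test_terminal_mutation_truncates_registers(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        mut = Mutation("c", "p", 3, "D", "E")
        protein = apply_mutation(ProteinRecord("p", seq), mut)
        regs = enumerate_mutant_registers(protein, mut, 9)
        assert [r.window.start for r in regs] == [1, 2, 3]

    def test_non_tcem_register_keeps_wildtype_motif(self, interior):
        protein, mut = interior
        wt = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        for r in enumerate_mutant_registers(protein, mut, 9):
            wt_pep = wt[r.window.start - 1 : r.window.start + 8]
            if not r.exposed:
                assert r.tcem.pentamer == extract_tcem_i(wt_pep).pentamer
            else:
                assert r.tcem.pentamer != extract_tcem_i(wt_pep).pentamer

    def test_offsets_are_contiguous(self, interior):
        protein, mut = interior
        offsets = [
            mutant_relative_index(r.window, mut)
            for r in enumerate_mutant_registers(protein, mut, 9)
        ]
        assert offsets == list(range(-8, 1))

    def test_offset_examples(self):
        m = Mutation("c", "p", 100, "A", "C")
        assert mutant_relative_index(PeptideWindow("p", 100, 9, "A" * 9), m) == 0
        assert mutant_relative_index(PeptideWindow("p", 92, 9, "A" * 9), m) == -8
        with pytest.raises(ValueError):
            mutant_relative_index(PeptideWindow("q", 92, 9, "A" * 9), m)
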