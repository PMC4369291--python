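import itertools

import pytest

from minmol.datasheet import Column, ColumnType, DataSheet
from minmol.findings import Severity
from minmol.fixtures import (
    atom_fragment,
    build_fixture,
    methyl_fragment,
    xr_substitutions,
)
from minmol.formula import formula_to_string
from minmol.model import Atom, Bond, Molecule
from minmol.validate import (
    EntryKind,
    GateDecision,
    classify_entry,
    enumerate_template,
    gate_entry,
    is_placeholder,
    validate_molecule,
)


class TestClassify:
    def test_benzene_is_a_molecule(self):
        from minmol.fixtures import benzene

        assert classify_entry(benzene()) is EntryKind.MOLECULE

    def test_placeholders_make_a_template(self):
        assert classify_entry(build_fixture("xr_template")) \
            is EntryKind.TEMPLATE

    def test_query_extension_makes_a_query(self):
        mol = Molecule([Atom("C"), Atom("C")],
                       [Bond(1, 2, 1, extensions=["qany-order"])])
        assert classify_entry(mol) is EntryKind.QUERY

    @pytest.mark.parametrize("token,expect", [
        ("X", True), ("R", True), ("R1", True), ("R12", True),
        ("x", False), ("r1", False), ("Rn", False), ("XX", False),
        ("Br", False),
    ])
    def test_placeholder_grammar_exact(self, token, expect):
        assert is_placeholder(token) is expect

    def test_defined_abbreviation_is_not_a_placeholder(self):
        # an atom labelled R1 with an inline definition is a molecule part
        from minmol.abbrev import set_definition

        mol = Molecule([Atom("R1")])
        set_definition(mol.atoms[0], methyl_fragment())
        assert classify_entry(mol) is EntryKind.MOLECULE


class TestRules:
    def _codes(self, mol, severity=None):
        fs = validate_molecule(mol)
        if severity:
            fs = [f for f in fs if f.severity is severity]
        return [f.code for f in fs]

    def test_uninterpretable_label_is_an_error(self):
        codes = self._codes(build_fixture("fe_dimer_naive"),
                            Severity.ERROR)
        assert codes == ["uninterpretable_label"] * 2

    def test_pentavalent_carbon_warns_not_errors(self):
        findings = validate_molecule(build_fixture("pentavalent_carbon"))
        assert [f.code for f in findings] == ["hypervalent_atom"]
        assert findings[0].severity is Severity.WARNING

    def test_covalent_salt_warns(self):
        codes = self._codes(build_fixture("nacl_covalent"))
        assert "covalent_salt" in codes
        assert "ambiguous_valence" not in codes  # Na has no default valence

    def test_pentavalent_nitro_warns(self):
        codes = self._codes(build_fixture("nitro_pentavalent"))
        assert "pentavalent_nitro" in codes

    def test_charge_separated_nitro_is_clean(self):
        mol = build_fixture("nitro_pentavalent")
        mol.atom(2).charge = 1
        mol.atom(3).charge = -1
        mol.bonds[1].order = 1
        assert self._codes(mol) == []

    def test_net_charge_info_on_single_component(self):
        findings = validate_molecule(build_fixture("methylammonium"))
        assert [(f.code, f.severity) for f in findings] \
            == [("net_charge", Severity.INFO)]

    def test_ambiguous_open_valence_metal_warns(self, sncl2):
        assert "ambiguous_valence" in self._codes(sncl2)

    @pytest.mark.parametrize("fix", ["sncl2_fixed_lonepair",
                                     "sncl2_fixed_hzero"])
    def test_explicit_disambiguation_silences_the_warning(self, fix):
        assert "ambiguous_valence" not in self._codes(build_fixture(fix))

    def test_template_without_recipe_is_an_error(self):
        codes = self._codes(build_fixture("xr_template"), Severity.ERROR)
        assert codes == ["template_without_recipe"]

    def test_validation_is_pure_and_stable(self, sncl2):
        a = validate_molecule(sncl2)
        b = validate_molecule(sncl2)
        assert a == b


class TestGate:
    def test_clean_molecule_accepted_with_formula(self, bromobenzene):
        result = gate_entry(bromobenzene)
        assert result.decision is GateDecision.ACCEPT
        assert formula_to_string(result.formulas["molecule"]) == "C6H5Br"

    def test_warnings_do_not_block(self):
        result = gate_entry(build_fixture("pentavalent_carbon"))
        assert result.decision is GateDecision.ACCEPT
        assert any(f.severity is Severity.WARNING for f in result.findings)

    def test_naive_dimer_rejected_machine_dimer_accepted(self):
        """The central asymmetry: the chemist-style drawing with CO/OC
        text labels is rejected as uninterpretable, while the same
        chemistry drawn with zero-order bonds and lone pairs passes with
        a clean formula."""
        naive = gate_entry(build_fixture("fe_dimer_naive"))
        assert naive.decision is GateDecision.REJECT
        assert any(f.code == "uninterpretable_label"
                   for f in naive.findings)

        machine = gate_entry(build_fixture("fe_dimer_machine"))
        assert machine.decision is GateDecision.ACCEPT
        (formula,) = machine.formulas.values()
        assert formula_to_string(formula) == "C14H10Fe2O4"
        assert formula.unknown_labels == []

    def test_sheet_rejection_locates_the_cell(self):
        sheet = DataSheet(columns=[Column("Mol", ColumnType.MOLECULE)])
        sheet.append_row()
        sheet.append_row()
        sheet.rows[0] = [build_fixture("bromobenzene_full")]
        sheet.rows[1] = [build_fixture("fe_dimer_naive")]
        result = gate_entry(sheet)
        assert result.decision is GateDecision.REJECT
        errors = [f for f in result.findings
                  if f.severity is Severity.ERROR]
        assert all("row 1" in f.locator for f in errors)

    def test_accept_implies_clean_formula_everywhere(self):
        for name in ("bromobenzene_full", "bromobenzene_ph",
                     "triethylsilane_meta", "fe_dimer_machine",
                     "ammonium_d4_bromide"):
            result = gate_entry(build_fixture(name))
            assert result.decision is GateDecision.ACCEPT
            for f in result.formulas.values():
                assert f.unknown_labels == []


class TestEnumeration:
    def test_x_r_template_gives_four_species(self):
        species = enumerate_template(build_fixture("xr_template"),
                                     xr_substitutions())
        assert len(species) == 4
        assert all(classify_entry(s) is EntryKind.MOLECULE
                   for s in species)

    def test_single_placeholder_single_fragment(self):
        template = Molecule([Atom("C"), Atom("X", 1.5, 0.0)],
                            [Bond(1, 2, 1)])
        out = enumerate_template(template, {"X": [atom_fragment("Cl")]})
        assert len(out) == 1
        assert out[0].atoms[1].element == "Cl"

    def test_three_sites_two_choices_each_gives_eight(self):
        template = Molecule([Atom("C")])
        for k, label in enumerate(["R1", "R2", "R3"], 1):
            template.add_atom(Atom(label, 1.5 * k, 1.5))
            template.add_bond(Bond(1, k + 1, 1))
        subs = {lb: [atom_fragment(el) for el in pair]
                for lb, pair in (("R1", ("F", "Cl")),
                                 ("R2", ("N", "O")),
                                 ("R3", ("S", "P")))}
        out = enumerate_template(template, subs)
        assert len(out) == 8
        assert len(out) <= 2 * 2 * 2

    def test_duplicate_species_removed(self):
        # identical substituents on symmetric sites collapse
        template = Molecule([Atom("C"), Atom("R1", -1.5, 0.0),
                             Atom("R2", 1.5, 0.0)],
                            [Bond(1, 2, 1), Bond(1, 3, 1)])
        subs = {"R1": [atom_fragment("F"), atom_fragment("Cl")],
                "R2": [atom_fragment("F"), atom_fragment("Cl")]}
        out = enumerate_template(template, subs)
        # F/Cl and Cl/F are the same graph: 3 distinct species, not 4
        assert len(out) == 3

    def test_missing_substitution_list_raises(self):
        with pytest.raises(ValueError, match="R"):
            enumerate_template(build_fixture("xr_template"),
                               {"X": [atom_fragment("F")]})

    def test_output_bounded_by_product(self):
        subs = xr_substitutions()
        bound = 1
        for frags in subs.values():
            bound *= len(frags)
        out = enumerate_template(build_fixture("xr_template"), subs)
        assert len(out) <= bound
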