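import pytest

from minmol.datasheet import (
    Column,
    ColumnType,
    DataSheet,
    DataSheetError,
    Extension,
    assemble_reaction_scheme,
    compose_sar_molecule,
    export_sdfile,
    parse_datasheet,
    repair_aspect,
    sdfile_to_datasheet,
    write_datasheet,
)
from minmol.fixtures import (
    SHEET_FIXTURES,
    atom_fragment,
    build_fixture,
    methyl_fragment,
)
from minmol.formula import formula_to_string, molecular_formula
from minmol.model import Atom, Bond, Molecule, check_graph


def _basic_sheet():
    sheet = DataSheet(columns=[Column("Mol", ColumnType.MOLECULE),
                               Column("Value", ColumnType.REAL)])
    for k in range(3):
        idx = sheet.append_row()
        sheet.rows[idx] = [build_fixture("bromobenzene_full"), 1.5 * k]
    return sheet


def test_parse_write_identity_basic():
    sheet = _basic_sheet()
    assert parse_datasheet(write_datasheet(sheet)) == sheet
    assert len(sheet.rows) == 3


@pytest.mark.parametrize("name", SHEET_FIXTURES)
def test_parse_write_identity_every_aspect_fixture(name):
    sheet = build_fixture(name)
    assert parse_datasheet(write_datasheet(sheet)) == sheet


def test_unknown_aspect_payload_survives_byte_identical():
    sheet = _basic_sheet()
    payload = '{"mystery": [1, 2, 3],\n  "spacing":  "\tpreserved"}'
    sheet.header_extensions.append(Extension("FutureThing", payload))
    text = write_datasheet(sheet)
    back = parse_datasheet(text)
    assert back.extension("FutureThing").payload == payload


def test_cell_type_errors_name_the_cell():
    xml = write_datasheet(_basic_sheet()).replace(
        '<Cell column="Value">0.0</Cell>',
        '<Cell column="Value">abc</Cell>', 1)
    with pytest.raises(DataSheetError, match="row 0.*Value"):
        parse_datasheet(xml)


def test_duplicate_column_names_rejected():
    sheet = _basic_sheet()
    with pytest.raises(DataSheetError, match="duplicate"):
        sheet.append_column("Mol", ColumnType.STRING)


def test_set_cell_enforces_types():
    sheet = _basic_sheet()
    with pytest.raises(DataSheetError, match="conform"):
        sheet.set_cell(0, "Value", "not a number")
    sheet.set_cell(0, "Value", None)  # null is always legal
    assert sheet.get_cell(0, "Value") is None


def test_empty_sheet_roundtrip():
    sheet = DataSheet()
    assert parse_datasheet(write_datasheet(sheet)) == sheet


class TestRepair:
    def test_deleted_substituent_column_restored_null(self):
        sheet = build_fixture("sar_sheet")
        sheet.delete_column("R1")
        repaired = repair_aspect(sheet, "SARTable")
        assert repaired.has_column("R1")
        i = repaired.column_index("R1")
        assert repaired.columns[i].type is ColumnType.MOLECULE
        assert all(row[i] is None for row in repaired.rows)
        # pre-existing data untouched
        assert repaired.get_cell(0, "Activity") == 12.5

    def test_intact_sheet_unchanged_and_idempotent(self):
        sheet = build_fixture("sar_sheet")
        once = repair_aspect(sheet, "SARTable")
        assert once == sheet
        assert repair_aspect(once, "SARTable") == once

    def test_unknown_aspect_name_raises(self):
        with pytest.raises(DataSheetError, match="unknown aspect"):
            repair_aspect(build_fixture("sar_sheet"), "FutureThing")

    @pytest.mark.parametrize("name,aspect", [
        ("reaction_sheet", "Reaction"),
        ("experiment_sheet_2step", "Experiment"),
        ("solvent_sheet", "Solvent"),
    ])
    def test_repair_restores_any_deleted_required_column(self, name, aspect):
        sheet = build_fixture(name)
        victim = sheet.aspects[aspect].required_columns()[0].name
        sheet.delete_column(victim)
        repaired = repair_aspect(sheet, aspect)
        assert repaired.has_column(victim)
        assert repair_aspect(repaired, aspect) == repaired


def test_unaware_editor_simulation_keeps_aspects_alive():
    """Generic row/cell/column edits through software that knows nothing
    about aspects must leave every aspect payload parseable, with repair
    a no-op or a pure column restoration."""
    for name in SHEET_FIXTURES:
        sheet = build_fixture(name)
        payloads = [(e.name, e.payload) for e in sheet.header_extensions]
        sheet.append_row()
        sheet.append_column("UnawareNote", ColumnType.STRING)
        sheet.set_cell(len(sheet.rows) - 1, "UnawareNote", "edited blind")
        if len(sheet.rows) > 1:
            sheet.delete_row(0)
        back = parse_datasheet(write_datasheet(sheet))
        assert [(e.name, e.payload)
                for e in back.header_extensions] == payloads
        for aspect_name in back.aspects:
            repaired = repair_aspect(back, aspect_name)
            extra = {c.name for c in repaired.columns} \
                - {c.name for c in back.columns}
            for col in extra:  # restorations only, null-filled
                ci = repaired.column_index(col)
                assert all(r[ci] is None for r in repaired.rows)


def test_editing_a_structure_cell_preserves_reaction_aspect():
    sheet = build_fixture("reaction_sheet")
    payload = sheet.extension("Reaction").payload
    sheet.set_cell(0, "Reactant1", build_fixture("cyclopentane_misdrawn"))
    back = parse_datasheet(write_datasheet(sheet))
    assert back.extension("Reaction").payload == payload
    steps = assemble_reaction_scheme(back, 0)
    assert len(steps) == 1


class TestComposeSAR:
    def test_methyl_graft_adds_one_carbon(self):
        scaffold = _scaffold_r1()
        before = molecular_formula(scaffold)
        assert before.unknown_labels == ["R1"]
        out = compose_sar_molecule(scaffold, {"R1": methyl_fragment()})
        assert check_graph(out) == []
        f = molecular_formula(out)
        # toluene: scaffold benzene (C6H5-) plus CH3
        assert formula_to_string(f) == "C7H8"

    def test_bare_hydrogen_substituent_restores_parent(self):
        out = compose_sar_molecule(_scaffold_r1(),
                                   {"R1": atom_fragment("H")})
        assert formula_to_string(molecular_formula(out)) == "C6H6"

    def test_missing_placeholder_mapping_raises(self):
        scaffold = _scaffold_r1()
        r2 = scaffold.add_atom(Atom("R2", 0.0, -3.0))
        scaffold.add_bond(Bond(4, r2, 1))
        with pytest.raises(DataSheetError, match="R2"):
            compose_sar_molecule(scaffold, {"R1": methyl_fragment()})


def _scaffold_r1():
    from minmol.fixtures import benzene

    mol = benzene()
    top = mol.atom(1)
    r1 = mol.add_atom(Atom("R1", top.x, top.y + 1.5))
    mol.add_bond(Bond(1, r1, 1))
    return mol


class TestReactionScheme:
    def test_single_step_roles(self):
        steps = assemble_reaction_scheme(build_fixture("reaction_sheet"), 0)
        assert len(steps) == 1
        roles = [(c.role, c.column) for c in steps[0]]
        assert roles == [("reactant", "Reactant1"),
                         ("reactant", "Reactant2"),
                         ("reagent", "Reagent1"),
                         ("product", "Product1")]
        assert isinstance(steps[0][0].value, Molecule)
        assert steps[0][2].value == "K2CO3"

    def test_two_step_experiment_orders_steps(self):
        steps = assemble_reaction_scheme(
            build_fixture("experiment_sheet_2step"), 0)
        assert len(steps) == 2
        assert steps[0][0].quantity == 2.5
        assert steps[1][0].column == "Step1Product"

    def test_sheet_without_aspect_raises(self):
        with pytest.raises(DataSheetError, match="aspect"):
            assemble_reaction_scheme(_basic_sheet(), 0)


class TestSDExport:
    def test_three_rows_three_records(self):
        text = export_sdfile(_basic_sheet(), "Mol")
        assert text.count("$$$$") == 3
        assert text.count("M  END") == 3

    def test_boolean_typing_lost_on_reimport(self):
        sheet = build_fixture("solvent_sheet")
        text = export_sdfile(sheet, "Solvent")
        back = sdfile_to_datasheet(text)
        green = next(c for c in back.columns if c.name == "Green")
        assert green.type is ColumnType.STRING  # was BOOLEAN upstream
        bp = next(c for c in back.columns if c.name == "BP")
        assert bp.type is ColumnType.REAL

    def test_aspect_dropped_but_molecules_and_formulas_survive(self):
        sheet = build_fixture("reaction_sheet")
        text = export_sdfile(sheet, "Product1")
        back = sdfile_to_datasheet(text)
        assert back.extension("Reaction") is None
        assert len(back.rows) == len(sheet.rows)
        for r in range(len(sheet.rows)):
            want = molecular_formula(sheet.get_cell(r, "Product1")).counts
            got = molecular_formula(back.get_cell(r, "Molecule")).counts
            assert got == want

    def test_non_molecule_column_rejected(self):
        with pytest.raises(DataSheetError, match="not molecule"):
            export_sdfile(_basic_sheet(), "Value")
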