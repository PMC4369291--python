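import pytest

from minmol.fixtures import MOLECULE_FIXTURES, build_fixture, random_organic
from minmol.formula import LEGACY, STRICT, formula_to_string, molecular_formula
from minmol.model import Atom, Bond, Molecule
from minmol.molfile import (
    MolfileError,
    parse_molfile,
    parse_sdfile,
    write_molfile,
)

PH_BR_MOLFILE = """\

  sketch  2D

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 Ph  0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 Br  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
M  END
"""


def _connectivity(mol):
    return sorted((frozenset((b.from_atom, b.to_atom)), b.order)
                  for b in mol.bonds), mol.num_atoms


def test_plain_text_abbreviation_molfile_flags_non_element():
    mol, findings = parse_molfile(PH_BR_MOLFILE)
    assert mol.num_atoms == 2
    assert mol.atoms[0].element == "Ph"
    assert [f.code for f in findings] == ["non_element_label"]
    assert "Ph" in findings[0].message


def test_sncl2_import_freezes_hydrogens_per_mode(sncl2):
    text, _ = write_molfile_naive_sncl2()
    legacy, _ = parse_molfile(text, LEGACY)
    strict, _ = parse_molfile(text, STRICT)
    assert legacy.atom(1).virtual_hydrogens == 2   # H2SnCl2 reading
    assert strict.atom(1).virtual_hydrogens == 0
    assert formula_to_string(molecular_formula(legacy)) == "Cl2H2Sn"
    assert formula_to_string(molecular_formula(strict)) == "Cl2Sn"


def write_molfile_naive_sncl2():
    # hand-assembled foreign molfile: no valence pinning, bare Sn
    lines = ["", "  other   2D", "",
             "  3  2  0  0  0  0  0  0  0  0999 V2000",
             "    0.0000    0.0000    0.0000 Sn  0  0  0  0  0  0  0  0"
             "  0  0  0  0",
             "   -1.2990   -0.7500    0.0000 Cl  0  0  0  0  0  0  0  0"
             "  0  0  0  0",
             "    1.2990   -0.7500    0.0000 Cl  0  0  0  0  0  0  0  0"
             "  0  0  0  0",
             "  1  2  1  0  0  0  0",
             "  1  3  1  0  0  0  0",
             "M  END"]
    return "\n".join(lines) + "\n", None


def test_counts_line_fixed_columns():
    mol = Molecule([Atom("C", float(i), 0.0) for i in range(4)],
                   [Bond(i, i + 1, 1) for i in range(1, 4)])
    text, _ = write_molfile(mol)
    counts = text.splitlines()[3]
    assert counts.startswith("  4  3")
    assert counts.endswith("999 V2000")


def test_bromobenzene_roundtrip_is_lossless(bromobenzene):
    text, loss = write_molfile(bromobenzene)
    assert len(loss) == 0
    back, findings = parse_molfile(text, LEGACY)
    assert findings == []
    assert formula_to_string(molecular_formula(back)) == "C6H5Br"
    assert _connectivity(back) == _connectivity(bromobenzene)


def test_zero_order_bonds_each_get_a_loss_entry():
    dimer = build_fixture("fe_dimer_machine")
    n_zero = sum(1 for b in dimer.bonds if b.order == 0)
    text, loss = write_molfile(dimer)
    assert sum(1 for e in loss.entries
               if e.code == "zero-order-bond") == n_zero
    # hydrogen pinning still preserves the formula downstream
    back, _ = parse_molfile(text, LEGACY)
    assert molecular_formula(back).counts == molecular_formula(dimer).counts


def test_abbreviation_export_expands_with_loss(bromobenzene_ph):
    text, loss = write_molfile(bromobenzene_ph)
    assert any(e.code == "abbreviation-expanded" for e in loss.entries)
    back, _ = parse_molfile(text, LEGACY)
    assert formula_to_string(molecular_formula(back)) == "C6H5Br"


def test_refuses_uninterpretable_labels():
    with pytest.raises(MolfileError, match="CO"):
        write_molfile(build_fixture("fe_dimer_naive"))


def test_isotopes_charges_radicals_roundtrip():
    mol = build_fixture("ammonium_d4_bromide")
    text, loss = write_molfile(mol)
    assert len(loss) == 0
    back, _ = parse_molfile(text, LEGACY)
    f = molecular_formula(back)
    assert f.counts == molecular_formula(mol).counts
    assert back.atom(1).charge == 1 and back.atom(6).charge == -1
    assert back.atom(2).isotope == 2


def test_write_parse_legacy_preserves_formula_for_octet_organics(rng):
    for _ in range(150):
        mol = random_organic(rng, rng.randint(2, 8))
        text, _ = write_molfile(mol)
        back, _ = parse_molfile(text, LEGACY)
        assert molecular_formula(back).counts == \
            molecular_formula(mol).counts


@pytest.mark.parametrize("name", [
    n for n in MOLECULE_FIXTURES if n not in ("fe_dimer_naive",
                                              "xr_template")])
def test_loss_report_empty_iff_roundtrip_faithful(name):
    mol = build_fixture(name)
    text, loss = write_molfile(mol)
    back, _ = parse_molfile(text, LEGACY)
    faithful = (_connectivity(back) == _connectivity(mol)
                and molecular_formula(back).counts
                == molecular_formula(mol).counts
                and not molecular_formula(mol).unknown_labels)
    assert bool(loss) == (not faithful)


def test_rdkit_agrees_on_exported_octet_structure(bromobenzene):
    """Cross-check: an independent toolkit reads our V2000 output and
    derives the same formula."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem
    from rdkit.Chem.rdMolDescriptors import CalcMolFormula

    text, _ = write_molfile(bromobenzene)
    rd = Chem.MolFromMolBlock(text)
    assert rd is not None
    assert CalcMolFormula(rd) == "C6H5Br"


class TestSDfile:
    def test_records_split_and_fields_parse(self):
        text1, _ = write_molfile(build_fixture("bromobenzene_full"))
        text2, _ = write_molfile(build_fixture("cyclopentane_misdrawn"))
        sd = (text1.rstrip("\n") + "\n> <Name>\nbromobenzene\n\n"
              "> <MP>\n-31\n\n$$$$\n"
              + text2.rstrip("\n") + "\n> <Name>\ncyclopentane\n\n$$$$\n")
        records = parse_sdfile(sd)
        assert len(records) == 2
        assert records[0][1] == {"Name": "bromobenzene", "MP": "-31"}
        assert records[1][1] == {"Name": "cyclopentane"}

    def test_truncated_record_raises(self):
        with pytest.raises(MolfileError):
            parse_sdfile("garbage\nwithout end\n$$$$\n")


def test_malformed_counts_line_raises():
    with pytest.raises(MolfileError, match="counts"):
        parse_molfile("\n\n\nnot a counts line\n")
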