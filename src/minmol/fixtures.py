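"""Programmatic fixture registry: every worked structure built in code.

Each fixture is constructed from primitives (no checked-in blobs), passes
the structural invariant checks, and round-trips through the serializer.
The set also deliberately exercises every validation rule at least once —
the misdrawings are as much part of the registry as the clean records.

Molecule fixtures
-----------------
``bromobenzene_full``        all 7 heavy atoms drawn out
``bromobenzene_ph``          2 nodes: Ph abbreviation + Br
``triethylsilane_full``      every heavy atom explicit (Si carries an
                             explicit hydrogen-count override of 1)
``triethylsilane_et3``       Si + three Et abbreviation nodes
``triethylsilane_meta``      a single abbreviation-of-abbreviations node
``sncl2_naive``              bare Sn with two Cl — the ambiguous drawing
``sncl2_fixed_lonepair``     Sn with unpaired=2 (lone pair occupies valence)
``sncl2_fixed_hzero``        Sn with an explicit hydrogen count of 0
``cyclopentane_misdrawn``    bare C5 ring (reads literally as C5H10)
``ammonium_d4_bromide``      ND4+ Br- ion pair, isotope-tagged hydrogens
``xr_template``              benzene scaffold with X and R placeholders
``fe_dimer_naive``           CO/OC text labels, wedge, methyl-like ring
                             stub — the human-friendly misdrawing
``fe_dimer_machine``         zero-order bonds + lone pairs; formula-safe
``nacl_covalent``            covalently bound salt
``nitro_pentavalent``        neutral pentavalent nitro group
``pentavalent_carbon``       carbon with five single bonds
``methylammonium``           single-component cation (net-charge notice)

Datasheet fixtures: ``sar_sheet``, ``reaction_sheet``,
``experiment_sheet_2step``, ``solvent_sheet``.
"""

from __future__ import annotations

import math
import random

from .abbrev import IDEAL_BOND, set_definition
from .datasheet import (
    Column,
    ColumnType,
    DataSheet,
    Extension,
    ExperimentAspect,
    PropertyColumn,
    ReactionAspect,
    ReactionStep,
    SARTableAspect,
    SolventAspect,
    SolventColumn,
)
from .formula import ATTACHMENT
from .model import AUTO, Atom, Bond, Molecule, Stereo


class UnknownFixtureError(KeyError):
    pass


def _ring(elements: list[str], order_pattern: list[int] | None = None,
          radius: float | None = None) -> Molecule:
    n = len(elements)
    radius = radius or IDEAL_BOND / (2 * math.sin(math.pi / n))
    mol = Molecule()
    for k, el in enumerate(elements):
        ang = math.pi / 2 + 2 * math.pi * k / n
        mol.add_atom(Atom(el, round(radius * math.cos(ang), 4),
                          round(radius * math.sin(ang), 4)))
    for k in range(n):
        order = order_pattern[k] if order_pattern else 1
        mol.add_bond(Bond(k + 1, (k + 1) % n + 1, order))
    return mol


def benzene() -> Molecule:
    return _ring(["C"] * 6, [2, 1, 2, 1, 2, 1])


def _bromobenzene_full() -> Molecule:
    mol = benzene()
    top = mol.atom(1)
    mol.add_atom(Atom("Br", top.x, round(top.y + IDEAL_BOND, 4)))
    mol.add_bond(Bond(1, 7, 1))
    return mol


def phenyl_fragment() -> Molecule:
    """Benzene ring with an attachment marker on C1."""
    frag = benzene()
    top = frag.atom(1)
    marker = frag.add_atom(Atom(ATTACHMENT, top.x,
                                round(top.y + IDEAL_BOND, 4)))
    frag.add_bond(Bond(1, marker, 1))
    return frag


def _bromobenzene_ph() -> Molecule:
    mol = Molecule()
    ph = Atom("Ph", 0.0, 0.0)
    set_definition(ph, phenyl_fragment())
    mol.add_atom(ph)
    mol.add_atom(Atom("Br", IDEAL_BOND, 0.0))
    mol.add_bond(Bond(1, 2, 1))
    return mol


def ethyl_fragment() -> Molecule:
    """CH3-CH2-* : the Et abbreviation fragment (implied formula C2H5)."""
    frag = Molecule()
    frag.add_atom(Atom("C", 0.0, 0.0))
    frag.add_atom(Atom("C", round(IDEAL_BOND * math.cos(math.radians(30)), 4),
                       round(IDEAL_BOND * 0.5, 4)))
    frag.add_atom(Atom(ATTACHMENT,
                       round(2 * IDEAL_BOND * math.cos(math.radians(30)), 4),
                       0.0))
    frag.add_bond(Bond(1, 2, 1))
    frag.add_bond(Bond(2, 3, 1))
    return frag


def _triethylsilane_full() -> Molecule:
    mol = Molecule()
    # Si is outside the automatic-hydrogen set, so its single hydrogen is
    # pinned explicitly; the 6 carbons stay automatic.
    mol.add_atom(Atom("Si", 0.0, 0.0, virtual_hydrogens=1))
    for k in range(3):
        ang = math.radians(90 + 120 * k)
        x1 = round(IDEAL_BOND * math.cos(ang), 4)
        y1 = round(IDEAL_BOND * math.sin(ang), 4)
        x2 = round(2 * IDEAL_BOND * math.cos(ang), 4)
        y2 = round(2 * IDEAL_BOND * math.sin(ang), 4)
        c1 = mol.add_atom(Atom("C", x1, y1))
        c2 = mol.add_atom(Atom("C", x2, y2))
        mol.add_bond(Bond(1, c1, 1))
        mol.add_bond(Bond(c1, c2, 1))
    return mol


def _triethylsilane_et3() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("Si", 0.0, 0.0, virtual_hydrogens=1))
    for k in range(3):
        ang = math.radians(90 + 120 * k)
        et = Atom("Et", round(IDEAL_BOND * math.cos(ang), 4),
                  round(IDEAL_BOND * math.sin(ang), 4))
        set_definition(et, ethyl_fragment())
        idx = mol.add_atom(et)
        mol.add_bond(Bond(1, idx, 1))
    return mol


def _triethylsilane_meta() -> Molecule:
    """Single meta-abbreviation node compiling Si plus the 3 ethyls."""
    inner = _triethylsilane_et3()
    marker = inner.add_atom(Atom(ATTACHMENT, 0.0, -IDEAL_BOND))
    # zero-order attachment: the whole-species abbreviation consumes no
    # valence anywhere
    inner.add_bond(Bond(1, marker, 0))
    mol = Molecule()
    node = Atom("SiHEt3", 0.0, 0.0)
    set_definition(node, inner)
    mol.add_atom(node)
    return mol


def _sncl2(fix: str | None) -> Molecule:
    mol = Molecule()
    sn = Atom("Sn", 0.0, 0.0)
    if fix == "lonepair":
        sn.unpaired = 2
    elif fix == "hzero":
        sn.virtual_hydrogens = 0
    mol.add_atom(sn)
    for sx in (-1, 1):
        idx = mol.add_atom(
            Atom("Cl", round(sx * IDEAL_BOND * math.cos(math.radians(30)), 4),
                 round(-IDEAL_BOND * 0.5, 4)))
        mol.add_bond(Bond(1, idx, 1))
    return mol


def _cyclopentane_misdrawn() -> Molecule:
    # a cyclopentadienyl ligand drawn as a bare ring of plain single
    # bonds: literally cyclopentane, C5H10
    return _ring(["C"] * 5)


def _ammonium_d4_bromide() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("N", 0.0, 0.0, charge=1))
    for k in range(4):
        ang = math.radians(45 + 90 * k)
        h = Atom("H", round(IDEAL_BOND * math.cos(ang), 4),
                 round(IDEAL_BOND * math.sin(ang), 4))
        h.set_isotope(2)
        idx = mol.add_atom(h)
        mol.add_bond(Bond(1, idx, 1))
    mol.add_atom(Atom("Br", 3 * IDEAL_BOND, 0.0, charge=-1))
    return mol


def _xr_template() -> Molecule:
    """Benzene scaffold carrying X (ring position 1) and R (position 4)."""
    mol = benzene()
    top, bottom = mol.atom(1), mol.atom(4)
    x_idx = mol.add_atom(Atom("X", top.x, round(top.y + IDEAL_BOND, 4)))
    mol.add_bond(Bond(1, x_idx, 1))
    r_idx = mol.add_atom(Atom("R", bottom.x, round(bottom.y - IDEAL_BOND, 4)))
    mol.add_bond(Bond(4, r_idx, 1))
    return mol


def atom_fragment(element: str, charge: int = 0,
                  bond_order: int = 1) -> Molecule:
    """A one-atom substituent fragment with its attachment marker."""
    frag = Molecule()
    frag.add_atom(Atom(element, 0.0, 0.0, charge=charge))
    frag.add_atom(Atom(ATTACHMENT, IDEAL_BOND, 0.0))
    frag.add_bond(Bond(1, 2, bond_order))
    return frag


def methyl_fragment() -> Molecule:
    return atom_fragment("C")


def xr_substitutions() -> dict[str, list[Molecule]]:
    """Two alternatives per placeholder — four distinct species."""
    return {"X": [atom_fragment("F"), atom_fragment("Cl")],
            "R": [methyl_fragment(), atom_fragment("O")]}


def _cp_ligand_ring() -> Molecule:
    """Cyclopentadienyl drawn formula-safely: two double bonds and one
    radical carbon, each carbon one hydrogen."""
    mol = _ring(["C"] * 5, [2, 1, 2, 1, 1])
    mol.atom(5).unpaired = 1
    return mol


def _fe_dimer_machine() -> Molecule:
    """Fp2 dimer with zero-order eta/dative bonds; formula C14H10Fe2O4."""
    mol = Molecule()
    for side, sx in ((0, -1.0), (1, 1.0)):
        fe = mol.add_atom(Atom("Fe", round(sx * 1.2, 4), 0.0))
        ring = _cp_ligand_ring()
        base = mol.num_atoms
        for a in ring.atoms:
            mol.add_atom(Atom(a.element, round(a.x + sx * 3.2, 4),
                              round(a.y + 2.2, 4), a.charge, a.unpaired,
                              a.virtual_hydrogens, list(a.extensions)))
        for b in ring.bonds:
            mol.add_bond(Bond(b.from_atom + base, b.to_atom + base, b.order))
        for k in range(5):  # eta-5 attachment, zero-order
            mol.add_bond(Bond(fe, base + k + 1, 0))
        for j in range(2):  # terminal carbonyls: carbene-like :C=O, dative
            cx = round(sx * (2.2 + 0.8 * j), 4)
            cy = round(-1.6 - 0.9 * j, 4)
            c = mol.add_atom(Atom("C", cx, cy, unpaired=2))
            o = mol.add_atom(Atom("O", round(cx + sx * 1.0, 4),
                                  round(cy - 1.1, 4)))
            mol.add_bond(Bond(c, o, 2))
            mol.add_bond(Bond(fe, c, 0))
    mol.add_bond(Bond(1, mol.num_atoms // 2 + 1, 1))  # Fe-Fe
    return mol


def _fe_dimer_naive() -> Molecule:
    """The human-friendly misdrawing as a machine would ingest it.

    Each ring is a plain single-bonded pentagon (literally cyclopentane,
    C5H10); the eta line from the metal to the ring centre becomes a
    methyl-like carbon; the terminal carbonyls are bare CO/OC text
    labels; the bridging carbonyl carbons sit between the metals with
    their oxygens lost to the label styling; a wedge marks the 3D
    effect.  Reads as C14H28Fe2[CO][OC]."""
    mol = Molecule()
    fe_idx: list[int] = []
    for side, sx in ((0, -1.0), (1, 1.0)):
        fe = mol.add_atom(Atom("Fe", round(sx * 1.2, 4), 0.0))
        fe_idx.append(fe)
        ring = _ring(["C"] * 5)
        base = mol.num_atoms
        for a in ring.atoms:
            mol.add_atom(Atom("C", round(a.x + sx * 3.2, 4),
                              round(a.y + 2.6, 4)))
        for b in ring.bonds:
            mol.add_bond(Bond(b.from_atom + base, b.to_atom + base, 1))
        # the line to the ring centre: a carbon node at the centroid,
        # bonded only to the metal -> a methyl ligand
        centroid = mol.add_atom(Atom("C", round(sx * 3.2, 4), 2.6))
        mol.add_bond(Bond(fe, centroid, 1,
                          Stereo.INCLINED if side == 0 else Stereo.FLAT))
        label = "CO" if side == 0 else "OC"
        idx = mol.add_atom(Atom(label, round(sx * 2.4, 4), -1.8))
        mol.add_bond(Bond(fe, idx, 1))
    # bridging carbonyl carbons, oxygens absorbed into the label styling
    for k, dy in ((0, 0.9), (1, -0.9)):
        c = mol.add_atom(Atom("C", 0.0, dy))
        mol.add_bond(Bond(fe_idx[0], c, 2 if k == 0 else 1))
        mol.add_bond(Bond(fe_idx[1], c, 1 if k == 0 else 2))
    mol.add_bond(Bond(fe_idx[0], fe_idx[1], 1))
    return mol


def _nacl_covalent() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("Na", 0.0, 0.0))
    mol.add_atom(Atom("Cl", IDEAL_BOND, 0.0))
    mol.add_bond(Bond(1, 2, 1))
    return mol


def _nitro_pentavalent() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("C", 0.0, 0.0))
    n = mol.add_atom(Atom("N", IDEAL_BOND, 0.0))
    o1 = mol.add_atom(Atom("O", round(IDEAL_BOND * 1.75, 4), 1.1))
    o2 = mol.add_atom(Atom("O", round(IDEAL_BOND * 1.75, 4), -1.1))
    mol.add_bond(Bond(1, n, 1))
    mol.add_bond(Bond(n, o1, 2))
    mol.add_bond(Bond(n, o2, 2))
    return mol


def _pentavalent_carbon() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("C", 0.0, 0.0))
    for k in range(5):
        ang = math.radians(90 + 72 * k)
        idx = mol.add_atom(Atom("C", round(IDEAL_BOND * math.cos(ang), 4),
                                round(IDEAL_BOND * math.sin(ang), 4)))
        mol.add_bond(Bond(1, idx, 1))
    return mol


def _methylammonium() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("C", 0.0, 0.0))
    mol.add_atom(Atom("N", IDEAL_BOND, 0.0, charge=1))
    mol.add_bond(Bond(1, 2, 1))
    return mol


# ---------------------------------------------------------------------------
# datasheet fixtures


def _sar_scaffold() -> Molecule:
    mol = benzene()
    top = mol.atom(1)
    r1 = mol.add_atom(Atom("R1", top.x, round(top.y + IDEAL_BOND, 4)))
    mol.add_bond(Bond(1, r1, 1))
    return mol


def _sar_sheet() -> DataSheet:
    from .datasheet import compose_sar_molecule

    aspect = SARTableAspect(
        scaffold="Scaffold", substituents=["R1"], molecule="Molecule",
        properties=[PropertyColumn("Activity", "uM", 0.0, 100.0)])
    sheet = DataSheet(columns=[
        Column("Scaffold", ColumnType.MOLECULE),
        Column("R1", ColumnType.MOLECULE),
        Column("Molecule", ColumnType.MOLECULE),
        Column("Activity", ColumnType.REAL)])
    sheet.header_extensions.append(
        Extension("SARTable", aspect.to_payload()))
    for frag, activity in ((methyl_fragment(), 12.5),
                           (atom_fragment("Cl"), 3.0)):
        idx = sheet.append_row()
        scaffold = _sar_scaffold()
        sheet.rows[idx] = [scaffold, frag,
                           compose_sar_molecule(scaffold, {"R1": frag}),
                           activity]
    return sheet


def _reaction_sheet() -> DataSheet:
    aspect = ReactionAspect(steps=[ReactionStep(
        reactants=["Reactant1", "Reactant2"], reagents=["Reagent1"],
        products=["Product1"])])
    sheet = DataSheet(columns=[
        Column("Reactant1", ColumnType.MOLECULE),
        Column("Reactant2", ColumnType.MOLECULE),
        Column("Reagent1", ColumnType.STRING),
        Column("Product1", ColumnType.MOLECULE)])
    sheet.header_extensions.append(
        Extension("Reaction", aspect.to_payload()))
    idx = sheet.append_row()
    sheet.rows[idx] = [_bromobenzene_full(), _methanol(), "K2CO3",
                       _anisole()]
    return sheet


def _methanol() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("C", 0.0, 0.0))
    mol.add_atom(Atom("O", IDEAL_BOND, 0.0))
    mol.add_bond(Bond(1, 2, 1))
    return mol


def _anisole() -> Molecule:
    mol = benzene()
    top = mol.atom(1)
    o = mol.add_atom(Atom("O", top.x, round(top.y + IDEAL_BOND, 4)))
    c = mol.add_atom(Atom("C", round(top.x + IDEAL_BOND, 4),
                          round(top.y + IDEAL_BOND * 1.5, 4)))
    mol.add_bond(Bond(1, o, 1))
    mol.add_bond(Bond(o, c, 1))
    return mol


def _experiment_sheet_2step() -> DataSheet:
    aspect = ExperimentAspect(
        steps=[ReactionStep(reactants=["Step1Reactant"],
                            reagents=["Step1Reagent"],
                            products=["Step1Product"]),
               ReactionStep(reactants=["Step1Product"],
                            products=["Step2Product"])],
        quantities={"Step1Reactant": "Step1Qty"})
    sheet = DataSheet(columns=[
        Column("Step1Reactant", ColumnType.MOLECULE),
        Column("Step1Reagent", ColumnType.STRING),
        Column("Step1Product", ColumnType.MOLECULE),
        Column("Step2Product", ColumnType.MOLECULE),
        Column("Step1Qty", ColumnType.REAL)])
    sheet.header_extensions.append(
        Extension("Experiment", aspect.to_payload()))
    idx = sheet.append_row()
    sheet.rows[idx] = [_methanol(), "HBr", _bromomethane(),
                       _methylammonium(), 2.5]
    return sheet


def _bromomethane() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("C", 0.0, 0.0))
    mol.add_atom(Atom("Br", IDEAL_BOND, 0.0))
    mol.add_bond(Bond(1, 2, 1))
    return mol


def _solvent_sheet() -> DataSheet:
    aspect = SolventAspect(columns=[
        SolventColumn("BP", "boiling_point", "degC", "real"),
        SolventColumn("Density", "density", "g/mL", "real"),
        SolventColumn("Hazard", "hazard_class", "", "string")])
    sheet = DataSheet(columns=[
        Column("Solvent", ColumnType.MOLECULE),
        Column("Name", ColumnType.STRING),
        Column("BP", ColumnType.REAL),
        Column("Density", ColumnType.REAL),
        Column("Hazard", ColumnType.STRING),
        Column("Green", ColumnType.BOOLEAN)])
    sheet.header_extensions.append(
        Extension("Solvent", aspect.to_payload()))
    idx = sheet.append_row()
    sheet.rows[idx] = [_methanol(), "methanol", 64.7, 0.792,
                       "flammable", True]
    idx = sheet.append_row()
    sheet.rows[idx] = [_water(), "water", 100.0, 1.0, None, True]
    return sheet


def _water() -> Molecule:
    mol = Molecule()
    mol.add_atom(Atom("O", 0.0, 0.0))
    return mol


_REGISTRY = {
    "bromobenzene_full": _bromobenzene_full,
    "bromobenzene_ph": _bromobenzene_ph,
    "triethylsilane_full": _triethylsilane_full,
    "triethylsilane_et3": _triethylsilane_et3,
    "triethylsilane_meta": _triethylsilane_meta,
    "sncl2_naive": lambda: _sncl2(None),
    "sncl2_fixed_lonepair": lambda: _sncl2("lonepair"),
    "sncl2_fixed_hzero": lambda: _sncl2("hzero"),
    "cyclopentane_misdrawn": _cyclopentane_misdrawn,
    "ammonium_d4_bromide": _ammonium_d4_bromide,
    "xr_template": _xr_template,
    "fe_dimer_machine": _fe_dimer_machine,
    "fe_dimer_naive": _fe_dimer_naive,
    "nacl_covalent": _nacl_covalent,
    "nitro_pentavalent": _nitro_pentavalent,
    "pentavalent_carbon": _pentavalent_carbon,
    "methylammonium": _methylammonium,
    "sar_sheet": _sar_sheet,
    "reaction_sheet": _reaction_sheet,
    "experiment_sheet_2step": _experiment_sheet_2step,
    "solvent_sheet": _solvent_sheet,
}

MOLECULE_FIXTURES = tuple(
    n for n in _REGISTRY if not n.endswith("_sheet")
    and n != "experiment_sheet_2step")
SHEET_FIXTURES = tuple(n for n in _REGISTRY if n not in MOLECULE_FIXTURES)


def fixture_names() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def build_fixture(name: str):
    """Build a registered fixture; raises for unknown names."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; known: {', '.join(_REGISTRY)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# randomized molecules (property-test material)


def random_organic(rng: random.Random, n_atoms: int = 8) -> Molecule:
    """A random connected molecule over C/N/O/P/S with orders 1-3 and
    charges in {-1, 0, +1}; coordinates on a jittered grid."""
    mol = Molecule()
    for i in range(n_atoms):
        el = rng.choice(["C", "C", "C", "N", "O", "P", "S"])
        charge = rng.choice([0, 0, 0, 0, -1, 1])
        mol.add_atom(Atom(el, round(i * 1.5 + rng.uniform(-0.2, 0.2), 4),
                          round(rng.uniform(-1.0, 1.0), 4), charge=charge))
    for i in range(2, n_atoms + 1):
        j = rng.randint(1, i - 1)
        mol.add_bond(Bond(j, i, rng.choice([1, 1, 1, 2, 3])))
    # occasionally close a ring
    if n_atoms >= 4 and rng.random() < 0.5:
        a, b = rng.sample(range(1, n_atoms + 1), 2)
        pair = frozenset((a, b))
        if all(frozenset((x.from_atom, x.to_atom)) != pair
               for x in mol.bonds):
            mol.add_bond(Bond(a, b, 1))
    return mol


def random_decorated(rng: random.Random, n_atoms: int = 6) -> Molecule:
    """Random molecule carrying unknown extension tokens, explicit
    hydrogen overrides and isotopes — read/modify/write material."""
    mol = random_organic(rng, n_atoms)
    for i, a in enumerate(mol.atoms, 1):
        if rng.random() < 0.4:
            a.extensions.append(
                f"zz:{rng.randint(0, 999)}\twith\ttabs"
                if rng.random() < 0.3 else f"custom{rng.randint(0, 99)}")
        if rng.random() < 0.25:
            a.virtual_hydrogens = rng.randint(0, 3)
        if rng.random() < 0.2:
            a.set_isotope(rng.choice([2, 13, 15]))
        if rng.random() < 0.15:
            a.extensions.append(f"m{rng.randint(1, 20)}")
    for b in mol.bonds:
        if rng.random() < 0.2:
            b.extensions.append(f"future-flag-{rng.randint(0, 9)}")
        if rng.random() < 0.15:
            b.stereo = rng.choice(list(Stereo))
    return mol
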