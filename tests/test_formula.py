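import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minmol.fixtures import build_fixture, random_organic
from minmol.formula import (
    LEGACY,
    STRICT,
    FormulaMap,
    formula_to_string,
    implicit_hydrogen_count,
    molecular_formula,
)
from minmol.model import Atom, Bond, Molecule
from oracles import formula_by_counting, strict_hydrogens_oracle


class TestImplicitHydrogens:
    def test_ring_carbon_gets_two(self):
        ring = build_fixture("cyclopentane_misdrawn")
        assert all(implicit_hydrogen_count(ring, i, STRICT) == 2
                   for i in range(1, 6))

    def test_tin_strict_vs_legacy(self, sncl2):
        # the classic divalent-tin ambiguity: strict adds nothing,
        # a group-14 legacy reader hydrogenates to SnH2Cl2
        assert implicit_hydrogen_count(sncl2, 1, STRICT) == 0
        assert implicit_hydrogen_count(sncl2, 1, LEGACY) == 2

    def test_explicit_override_wins_in_both_modes(self):
        fixed = build_fixture("sncl2_fixed_hzero")
        assert implicit_hydrogen_count(fixed, 1, STRICT) == 0
        assert implicit_hydrogen_count(fixed, 1, LEGACY) == 0

    def test_lone_pair_occupies_valence(self):
        fixed = build_fixture("sncl2_fixed_lonepair")
        assert implicit_hydrogen_count(fixed, 1, LEGACY) == 0

    @pytest.mark.parametrize("element,charge,expect", [
        ("O", -1, 1),   # hydroxide
        ("N", +1, 4),   # ammonium
        ("C", -1, 3),   # carbanion (methanide from a bare atom)
        ("C", +1, 3),   # carbenium
        ("S", 0, 2),    # hydrogen sulfide
    ])
    def test_charged_single_atoms(self, element, charge, expect):
        mol = Molecule([Atom(element, charge=charge)])
        assert implicit_hydrogen_count(mol, 1, STRICT) == expect

    def test_multivalent_sulfur_steps_up(self):
        # sulfone-like S with bond-order sum 6 takes valence 6, no H
        mol = Molecule([Atom("S"), Atom("O"), Atom("O"), Atom("C")],
                       [Bond(1, 2, 2), Bond(1, 3, 2), Bond(1, 4, 1)])
        assert implicit_hydrogen_count(mol, 1, STRICT) == 1  # 6 - 5
        mol.add_atom(Atom("C"))
        mol.add_bond(Bond(1, 5, 1))
        assert implicit_hydrogen_count(mol, 1, STRICT) == 0

    def test_zero_order_bonds_consume_nothing(self):
        mol = Molecule([Atom("C"), Atom("Fe")], [Bond(1, 2, 0)])
        assert implicit_hydrogen_count(mol, 1, STRICT) == 4

    def test_unknown_atom_index_raises(self):
        with pytest.raises(IndexError):
            implicit_hydrogen_count(Molecule([Atom("C")]), 5)

    def test_strict_matches_bruteforce_oracle_on_random_organics(self):
        rng = random.Random(11)
        for _ in range(1000):
            mol = random_organic(rng, rng.randint(2, 9))
            for i, atom in enumerate(mol.atoms, 1):
                expect = strict_hydrogens_oracle(
                    atom.element, [b.order for b in mol.bonds_of(i)],
                    atom.unpaired, atom.charge)
                assert implicit_hydrogen_count(mol, i, STRICT) == expect


class TestMolecularFormula:
    @pytest.mark.parametrize("name", [
        "triethylsilane_full", "triethylsilane_et3", "triethylsilane_meta"])
    def test_triethylsilane_at_every_abbreviation_depth(self, name):
        f = molecular_formula(build_fixture(name))
        assert formula_to_string(f) == "C6H16Si"

    def test_deuterated_ammonium_bromide(self):
        f = molecular_formula(build_fixture("ammonium_d4_bromide"))
        assert f.counts[("H", 2)] == 4
        assert f.counts[("N", 0)] == 1
        assert f.counts[("Br", 0)] == 1
        assert ("H", 0) not in f.counts  # no natural-abundance hydrogen

    def test_unknown_label_lands_in_brackets(self):
        mol = Molecule([Atom("CO")])
        f = molecular_formula(mol)
        assert f.unknown_labels == ["CO"]
        assert f.counts == {}

    def test_formula_invariant_under_reordering(self, rng):
        for _ in range(25):
            mol = random_organic(rng, 7)
            perm = list(range(1, 8))
            rng.shuffle(perm)
            inv = {old: new for new, old in enumerate(perm, 1)}
            shuffled = Molecule(
                [mol.atom(i).copy() for i in perm],
                [Bond(inv[b.from_atom], inv[b.to_atom], b.order, b.stereo)
                 for b in mol.bonds])
            assert molecular_formula(shuffled) == molecular_formula(mol)

    def test_formula_invariant_under_kekule_shift(self):
        # alternate double-bond placement with identical per-atom sums
        a = Molecule([Atom("C") for _ in range(6)],
                     [Bond(i, i % 6 + 1, 2 - i % 2) for i in range(1, 7)])
        b = Molecule([Atom("C") for _ in range(6)],
                     [Bond(i, i % 6 + 1, 1 + i % 2) for i in range(1, 7)])
        assert molecular_formula(a) == molecular_formula(b)

    def test_monotone_in_explicit_hydrogens(self, rng):
        for _ in range(25):
            mol = random_organic(rng, 6)
            i = rng.randint(1, 6)
            mol.atom(i).virtual_hydrogens = rng.randint(0, 3)
            before = molecular_formula(mol).total("H")
            mol.atom(i).virtual_hydrogens += 1
            assert molecular_formula(mol).total("H") == before + 1

    def test_matches_counting_oracle_on_random_molecules(self, rng):
        for _ in range(200):
            mol = random_organic(rng, rng.randint(2, 8))
            assert molecular_formula(mol).counts == formula_by_counting(mol)


class TestFormulaToString:
    @pytest.mark.parametrize("counts,unknown,expect", [
        ({("C", 0): 6, ("H", 0): 16, ("Si", 0): 1}, [], "C6H16Si"),
        ({}, [], ""),
        ({("C", 0): 2, ("H", 0): 5}, [], "C2H5"),
        # Hill order without carbon is plain alphabetical
        ({("Br", 0): 1, ("H", 2): 4, ("N", 0): 1}, [], "Br[2H]4N"),
        ({("C", 0): 14, ("H", 0): 28, ("Fe", 0): 2}, ["CO", "OC"],
         "C14H28Fe2[CO][OC]"),
    ])
    def test_rendering(self, counts, unknown, expect):
        assert formula_to_string(FormulaMap(dict(counts), list(unknown))) \
            == expect


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 4), st.integers(-1, 1), st.integers(0, 2),
       st.sampled_from("CNOPS"))
def test_hydrogen_count_never_negative_and_matches_oracle(
        degree, charge, unpaired, element):
    mol = Molecule([Atom(element, charge=charge, unpaired=unpaired)])
    for k in range(degree):
        mol.add_atom(Atom("C", 1.5 * (k + 1), 0.0))
        mol.add_bond(Bond(1, k + 2, 1))
    got = implicit_hydrogen_count(mol, 1, STRICT)
    assert got >= 0
    assert got == strict_hydrogens_oracle(element, [1] * degree,
                                          unpaired, charge)
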