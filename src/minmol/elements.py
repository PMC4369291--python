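"""Periodic-table data used by formula inference and validation.

The data model itself never interprets element tokens; only the modules in
this file's client list (formula, validation, molfile interop) assign
chemical meaning to them.
"""

from __future__ import annotations

# All 118 IUPAC symbols, in atomic-number order.
SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

ELEMENT_SET: frozenset[str] = frozenset(SYMBOLS)
ATOMIC_NUMBER: dict[str, int] = {s: i + 1 for i, s in enumerate(SYMBOLS)}

# Elements that receive automatically calculated hydrogens in strict mode.
AUTO_HYDROGEN_ELEMENTS: frozenset[str] = frozenset({"C", "N", "O", "P", "S"})

# Strict-mode valence table: allowed valences in ascending order; the
# smallest one >= the occupied valence is chosen before charge adjustment.
STRICT_VALENCES: dict[str, tuple[int, ...]] = {
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
}

# Legacy group-based default valences, emulating common Molfile readers.
# Elements absent from this table default to 0.
LEGACY_VALENCES: dict[str, int] = {
    "B": 3,
    "C": 4, "Si": 4, "Ge": 4, "Sn": 4, "Pb": 4,
    "N": 3, "P": 3, "As": 3, "Sb": 3,
    "O": 2, "S": 2, "Se": 2, "Te": 2,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "At": 1,
}

# Carbon-group elements: charge reduces the available valence (|charge|
# subtracted) instead of adding to it.
CARBON_GROUP: frozenset[str] = frozenset({"C", "Si", "Ge", "Sn", "Pb"})

ALKALI_METALS: frozenset[str] = frozenset({"Li", "Na", "K", "Rb", "Cs", "Fr"})
HALOGENS: frozenset[str] = frozenset({"F", "Cl", "Br", "I", "At"})


def is_element(token: str) -> bool:
    """True if *token* is a periodic-table symbol."""
    return token in ELEMENT_SET
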