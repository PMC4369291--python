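"""Independent oracles used by the test suite.

These deliberately re-derive expected values by direct search rather than
calling the library's own arithmetic, so agreement is evidence and not
tautology.
"""

from __future__ import annotations

_DECISION_TABLE = {"C": (4,), "N": (3,), "O": (2,), "P": (3, 5),
                   "S": (2, 4, 6)}


def strict_hydrogens_oracle(element: str, bond_orders: list[int],
                            unpaired: int, charge: int) -> int:
    """Brute-force hydrogen count under the strict decision table.

    Searches h downward for the value satisfying the valence equation
    occupied + h == adjusted_valence, clamping at zero.
    """
    if element not in _DECISION_TABLE:
        return 0
    occupied = sum(bond_orders) + unpaired
    allowed = _DECISION_TABLE[element]
    base = next((v for v in allowed if v >= occupied), allowed[-1])
    adjusted = base - abs(charge) if element == "C" else base + charge
    for h in range(16, -1, -1):
        if occupied + h == adjusted:
            return h
    return 0


def formula_by_counting(mol) -> dict[tuple[str, int], int]:
    """Formula computed by per-atom enumeration using the brute-force
    hydrogen oracle; explicit overrides honoured."""
    from minmol.elements import is_element
    from minmol.formula import ATTACHMENT

    counts: dict[tuple[str, int], int] = {}

    def bump(el: str, mass: int, n: int = 1) -> None:
        if n:
            counts[(el, mass)] = counts.get((el, mass), 0) + n

    for i, atom in enumerate(mol.atoms, 1):
        if atom.element == ATTACHMENT or not is_element(atom.element):
            continue
        bump(atom.element, atom.isotope)
        if atom.virtual_hydrogens is not None:
            bump("H", 0, atom.virtual_hydrogens)
        else:
            orders = [b.order for b in mol.bonds_of(i)]
            bump("H", 0, strict_hydrogens_oracle(
                atom.element, orders, atom.unpaired, atom.charge))
    return counts
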