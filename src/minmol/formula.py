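"""Deterministic molecular-formula inference.

The guiding question: can an algorithm determine the molecular formula of
a drawing correctly and unambiguously?  Two hydrogen models are provided:

``STRICT``
    Hydrogens are calculated automatically only for C, N, O, P and S, and
    are zero for every other element.  Base valences are C=4, N=3, O=2,
    P∈{3,5}, S∈{2,4,6}; the multivalent elements take the smallest allowed
    valence >= the occupied valence.  The occupied valence is the sum of
    bond orders (zero-order bonds contribute nothing) plus the
    unpaired-electron count.  Charge adjusts the valence: carbon loses
    |charge|, the heteroatoms gain the signed charge.  The hydrogen count
    is ``max(0, adjusted_valence - occupied)``.

``LEGACY``
    Emulates the group-based default-valence interpretation common in
    Molfile readers (B=3; C,Si,Ge,Sn,Pb=4; N,P,As,Sb=3; O,S,Se,Te=2;
    halogens=1; everything else 0), with the same occupancy arithmetic.
    This is the model that reads a bare SnCl2 drawing as H2SnCl2; it
    exists to reproduce that behaviour on import, never as a default.

An explicit per-atom virtual-hydrogen override always wins over either
model.  Zero-order bonds never consume valence, which is what keeps
dative/multicentre drawings formula-safe.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .elements import (
    AUTO_HYDROGEN_ELEMENTS,
    CARBON_GROUP,
    LEGACY_VALENCES,
    STRICT_VALENCES,
    is_element,
)
from .model import Molecule

#: Marker element for abbreviation-fragment attachment points.  It is a
#: pseudo-atom: it consumes bond order like any neighbour but contributes
#: nothing to the formula.
ATTACHMENT = "*"


class HydrogenMode(enum.Enum):
    STRICT = "strict"
    LEGACY = "legacy"


STRICT = HydrogenMode.STRICT
LEGACY = HydrogenMode.LEGACY


class FormulaError(ValueError):
    pass


@dataclass
class FormulaMap:
    """Element(+isotope) counts plus ordered uninterpretable labels.

    Keys of ``counts`` are ``(element, mass)`` with mass 0 meaning natural
    abundance.  ``unknown_labels`` keeps first-encounter drawing order and
    may repeat.
    """

    counts: dict[tuple[str, int], int] = field(default_factory=dict)
    unknown_labels: list[str] = field(default_factory=list)

    def add(self, element: str, mass: int = 0, n: int = 1) -> None:
        if n == 0:
            return
        key = (element, mass)
        self.counts[key] = self.counts.get(key, 0) + n
        if self.counts[key] == 0:
            del self.counts[key]

    def total(self, element: str) -> int:
        """Count over all isotopes of *element*."""
        return sum(v for (el, _), v in self.counts.items() if el == element)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FormulaMap):
            return NotImplemented
        return (self.counts == other.counts
                and self.unknown_labels == other.unknown_labels)


def implicit_hydrogen_count(
    mol: Molecule,
    atom_index: int,
    mode: HydrogenMode = STRICT,
    valence_overrides: dict[str, int] | None = None,
) -> int:
    """Virtual hydrogens on atom *atom_index* (1-based).

    An explicit per-atom override is returned verbatim regardless of mode.
    ``valence_overrides`` (element -> default valence) patches the LEGACY
    table only; it exists for configuration-driven import emulation.
    """
    atom = mol.atom(atom_index)
    if atom.virtual_hydrogens is not None:
        return atom.virtual_hydrogens
    el = atom.element
    occupied = mol.bond_order_sum(atom_index) + atom.unpaired

    if mode is STRICT:
        if el not in AUTO_HYDROGEN_ELEMENTS:
            return 0
        allowed = STRICT_VALENCES[el]
        base = next((v for v in allowed if v >= occupied), allowed[-1])
        if el == "C":
            adjusted = base - abs(atom.charge)
        else:
            adjusted = base + atom.charge
        return max(0, adjusted - occupied)

    table = dict(LEGACY_VALENCES)
    if valence_overrides:
        table.update(valence_overrides)
    base = table.get(el, 0)
    if base == 0:
        return 0
    if el in CARBON_GROUP:
        adjusted = base - abs(atom.charge)
    else:
        adjusted = base + atom.charge
    return max(0, adjusted - occupied)


def molecular_formula(
    mol: Molecule,
    expand_abbreviations: bool = True,
    mode: HydrogenMode = STRICT,
) -> FormulaMap:
    """Sum explicit atoms plus inferred hydrogens into a :class:`FormulaMap`.

    Isotope-extended atoms are counted under their ``(element, mass)`` key.
    Attachment markers (``*``) are skipped entirely (their bond still
    occupies valence on the neighbour).  Atoms whose token is not an
    element and carries no abbreviation definition land in
    ``unknown_labels``; with *expand_abbreviations* set, defined
    abbreviations are expanded fully before counting.
    """
    work = mol
    if expand_abbreviations and any(a.has_abbreviation for a in mol.atoms):
        from .abbrev import expand_fully  # local import: avoids a cycle

        work = expand_fully(mol)

    out = FormulaMap()
    for i, atom in enumerate(work.atoms, start=1):
        el = atom.element
        if el == ATTACHMENT:
            continue
        if is_element(el):
            out.add(el, atom.isotope)
            h = implicit_hydrogen_count(work, i, mode)
            out.add("H", 0, h)
        else:
            out.unknown_labels.append(el)
    return out


def _hill_key(item: tuple[tuple[str, int], int],
              has_carbon: bool) -> tuple:
    (el, mass), _ = item
    if has_carbon:
        if el == "C":
            group = 0
        elif el == "H":
            group = 1
        else:
            group = 2
    else:
        group = 2
    return (group, el, mass)


def formula_to_string(f: FormulaMap) -> str:
    """Hill-order rendering: C, H, then alphabetical (all alphabetical when
    no carbon is present).  Isotopes render as ``[2H]4``; uninterpretable
    labels are appended bracketed, in drawing order."""
    has_carbon = any(el == "C" for el, _ in f.counts)
    parts: list[str] = []
    for (el, mass), n in sorted(f.counts.items(),
                                key=lambda it: _hill_key(it, has_carbon)):
        sym = f"[{mass}{el}]" if mass else el
        parts.append(sym if n == 1 else f"{sym}{n}")
    for label in f.unknown_labels:
        parts.append(f"[{label}]")
    return "".join(parts)
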