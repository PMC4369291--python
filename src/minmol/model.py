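"""Core 2D molecule data model: atoms, bonds, extensions, invariants.

The model is deliberately minimal.  An atom is an element token (any
non-empty string), a 2D position in quasi-Ångström units (idealized bond
length 1.5, y increases upward), a formal charge, an unpaired-electron
count, a virtual-hydrogen setting, and an ordered list of opaque extension
tokens.  A bond is a pair of 1-based atom indices, an integer order in
0..5, a stereo drawing style, and its own extension list.

Chemical meaning (is this token an element? how many hydrogens?) is never
assigned here; a non-element token simply makes the record a template,
query or abbreviation placeholder, which downstream modules classify.

Reserved extension prefixes (single letter, payload follows directly):

====== =========================================================
prefix meaning
====== =========================================================
``z``  z coordinate (float) — presence implies a 3D conformation
``i``  isotope mass number (int; 0 = natural abundance)
``m``  mapping number (int)
``q``  query expression (opaque)
``a``  inline abbreviation: serialized fragment document
====== =========================================================

A token whose payload does not parse under its prefix is treated as
unknown and carried verbatim — forward compatibility is the point.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

#: Sentinel for automatically calculated virtual hydrogens.
AUTO: Optional[int] = None


class Stereo(enum.Enum):
    """Bond drawing style; stored, never chemically interpreted."""

    FLAT = "F"
    INCLINED = "I"
    DECLINED = "D"
    UNKNOWN = "U"


_STEREO_BY_CODE = {s.value: s for s in Stereo}


@dataclass
class Atom:
    element: str
    x: float = 0.0
    y: float = 0.0
    charge: int = 0
    unpaired: int = 0
    virtual_hydrogens: Optional[int] = AUTO  # AUTO (None) or explicit >= 0
    extensions: list[str] = field(default_factory=list)

    # -- reserved-extension accessors ------------------------------------

    @property
    def isotope(self) -> int:
        """Mass number from the isotope extension; 0 = natural abundance."""
        for tok in self.extensions:
            if tok.startswith("i"):
                try:
                    return int(tok[1:])
                except ValueError:
                    continue
        return 0

    def set_isotope(self, mass: int) -> None:
        self.extensions = [
            t for t in self.extensions
            if not (t.startswith("i") and _is_int(t[1:]))
        ]
        if mass:
            self.extensions.append(f"i{mass}")

    @property
    def mapping(self) -> int:
        for tok in self.extensions:
            if tok.startswith("m"):
                try:
                    return int(tok[1:])
                except ValueError:
                    continue
        return 0

    @property
    def z(self) -> Optional[float]:
        for tok in self.extensions:
            if tok.startswith("z"):
                try:
                    return float(tok[1:])
                except ValueError:
                    continue
        return None

    @property
    def abbreviation_text(self) -> Optional[str]:
        """Raw serialized fragment carried by the abbreviation extension."""
        for tok in self.extensions:
            if tok.startswith("a") and len(tok) > 1:
                return tok[1:]
        return None

    @property
    def has_abbreviation(self) -> bool:
        return self.abbreviation_text is not None

    @property
    def query_tokens(self) -> list[str]:
        return [t[1:] for t in self.extensions
                if t.startswith("q") and len(t) > 1]

    def copy(self) -> "Atom":
        return replace(self, extensions=list(self.extensions))


@dataclass
class Bond:
    from_atom: int  # 1-based
    to_atom: int    # 1-based
    order: int = 1
    stereo: Stereo = Stereo.FLAT
    extensions: list[str] = field(default_factory=list)

    @property
    def query_tokens(self) -> list[str]:
        return [t[1:] for t in self.extensions
                if t.startswith("q") and len(t) > 1]

    def other(self, idx: int) -> int:
        return self.to_atom if idx == self.from_atom else self.from_atom

    def copy(self) -> "Bond":
        return replace(self, extensions=list(self.extensions))


@dataclass
class Violation:
    """A structural-invariant failure; data, not an exception."""

    locator: str   # e.g. "atom 3" / "bond 2"
    rule: str      # stable rule identifier
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.locator}: {self.rule}: {self.message}"


@dataclass
class Molecule:
    """An ordered atom list plus an ordered bond list.

    The graph may be disconnected (mixtures and salt pairs are legal).
    Atom indices in bonds are 1-based, matching the serialized forms.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    # -- basic accessors -------------------------------------------------

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    def atom(self, idx: int) -> Atom:
        """1-based access."""
        if not 1 <= idx <= len(self.atoms):
            raise IndexError(f"atom index {idx} out of range 1..{len(self.atoms)}")
        return self.atoms[idx - 1]

    def bonds_of(self, idx: int) -> list[Bond]:
        return [b for b in self.bonds if idx in (b.from_atom, b.to_atom)]

    def neighbours(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self.bonds_of(idx)]

    def bond_order_sum(self, idx: int) -> int:
        return sum(b.order for b in self.bonds_of(idx))

    # -- mutation --------------------------------------------------------

    def add_atom(self, atom: Atom) -> int:
        self.atoms.append(atom)
        return len(self.atoms)

    def add_bond(self, bond: Bond) -> int:
        self.bonds.append(bond)
        return len(self.bonds)

    def delete_atom(self, idx: int) -> None:
        """Remove atom *idx* and every bond touching it; reindex the rest."""
        self.atom(idx)  # bounds check
        self.atoms.pop(idx - 1)
        kept: list[Bond] = []
        for b in self.bonds:
            if idx in (b.from_atom, b.to_atom):
                continue
            nb = b.copy()
            if nb.from_atom > idx:
                nb.from_atom -= 1
            if nb.to_atom > idx:
                nb.to_atom -= 1
            kept.append(nb)
        self.bonds = kept

    def copy(self) -> "Molecule":
        return Molecule([a.copy() for a in self.atoms],
                        [b.copy() for b in self.bonds])

    # -- structure -------------------------------------------------------

    def connected_components(self) -> list[list[int]]:
        """1-based atom indices grouped by connectivity, in first-seen order."""
        adj: dict[int, list[int]] = {i: [] for i in range(1, len(self.atoms) + 1)}
        for b in self.bonds:
            if b.from_atom in adj and b.to_atom in adj:
                adj[b.from_atom].append(b.to_atom)
                adj[b.to_atom].append(b.from_atom)
        seen: set[int] = set()
        comps: list[list[int]] = []
        for start in range(1, len(self.atoms) + 1):
            if start in seen:
                continue
            comp = [start]
            seen.add(start)
            queue = [start]
            while queue:
                u = queue.pop()
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        comp.append(v)
                        queue.append(v)
            comps.append(sorted(comp))
        return comps

    def distance(self, i: int, j: int) -> float:
        a, b = self.atom(i), self.atom(j)
        return math.hypot(a.x - b.x, a.y - b.y)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# operations


def heavy_atom_count(mol: Molecule) -> int:
    """Number of atom nodes whose element token is not ``H``.

    Abbreviation placeholders count as a single node each; no expansion
    is performed.
    """
    return sum(1 for a in mol.atoms if a.element != "H")


def net_formal_charge(mol: Molecule) -> int:
    """Sum of formal charges over all atoms."""
    return sum(a.charge for a in mol.atoms)


def check_graph(mol: Molecule) -> list[Violation]:
    """Verify every structural invariant; returns violations, never raises."""
    out: list[Violation] = []
    n = len(mol.atoms)
    for i, a in enumerate(mol.atoms, start=1):
        loc = f"atom {i}"
        if not a.element:
            out.append(Violation(loc, "empty-element", "element token is empty"))
        if a.unpaired < 0:
            out.append(Violation(loc, "negative-unpaired",
                                 f"unpaired count {a.unpaired} < 0"))
        if a.virtual_hydrogens is not None and a.virtual_hydrogens < 0:
            out.append(Violation(loc, "negative-hydrogens",
                                 f"explicit hydrogen count {a.virtual_hydrogens} < 0"))
        n_abbrev = sum(1 for t in a.extensions
                       if t.startswith("a") and len(t) > 1)
        if n_abbrev > 1:
            out.append(Violation(loc, "multiple-abbreviations",
                                 f"{n_abbrev} abbreviation extensions"))
        n_iso = sum(1 for t in a.extensions
                    if t.startswith("i") and _is_int(t[1:]))
        if n_iso > 1:
            out.append(Violation(loc, "multiple-isotopes",
                                 f"{n_iso} isotope extensions"))
    seen_pairs: set[frozenset[int]] = set()
    for j, b in enumerate(mol.bonds, start=1):
        loc = f"bond {j}"
        for end in (b.from_atom, b.to_atom):
            if not 1 <= end <= n:
                out.append(Violation(loc, "dangling-bond",
                                     f"references atom {end} of {n}"))
        if b.from_atom == b.to_atom:
            out.append(Violation(loc, "self-bond",
                                 f"both ends on atom {b.from_atom}"))
        if b.order not in (0, 1, 2, 3, 4, 5):
            out.append(Violation(loc, "bad-order",
                                 f"order {b.order} outside 0..5"))
        pair = frozenset((b.from_atom, b.to_atom))
        if len(pair) == 2 and 1 <= b.from_atom <= n and 1 <= b.to_atom <= n:
            if pair in seen_pairs:
                out.append(Violation(loc, "duplicate-bond",
                                     f"second bond between atoms "
                                     f"{min(pair)} and {max(pair)}"))
            seen_pairs.add(pair)
    return out
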