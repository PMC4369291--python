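"""Inline abbreviations: definition, recursive expansion, subsumption.

An abbreviation placeholder is an atom whose label (e.g. ``Ph``, ``Et``)
is displayed in lieu of an element symbol and whose defining fragment
travels inside the same record as an ``a``-prefixed extension token.  The
fragment contains exactly one attachment marker — a pseudo-atom with
element ``*`` bonded to the attachment atom — so it is fully
self-contained: there is no universal abbreviation dictionary, and this
package deliberately ships none.

Fragments may themselves contain abbreviation placeholders (nesting);
expansion is a fixpoint and definition cycles are detected by label chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .formula import ATTACHMENT
from .model import Atom, Bond, Molecule, check_graph

IDEAL_BOND = 1.5


class AbbreviationError(ValueError):
    pass


class CyclicDefinitionError(AbbreviationError):
    def __init__(self, chain: tuple[str, ...]):
        self.chain = chain
        super().__init__("cyclic abbreviation definition: "
                         + " -> ".join(chain))


@dataclass
class AbbreviationDef:
    """A display label plus its defining fragment.

    The fragment holds exactly one ``*`` attachment marker; the marker is
    deleted when the fragment is spliced into a host molecule.
    """

    label: str
    fragment: Molecule

    def validate(self) -> None:
        markers = [i for i, a in enumerate(self.fragment.atoms, 1)
                   if a.element == ATTACHMENT]
        if len(markers) != 1:
            raise AbbreviationError(
                f"fragment for '{self.label}' has {len(markers)} attachment "
                f"points; exactly 1 required")
        viols = [v for v in check_graph(self.fragment)]
        if viols:
            raise AbbreviationError(
                f"fragment for '{self.label}' is invalid: {viols[0]}")
        if len(self.fragment.bonds_of(markers[0])) != 1:
            raise AbbreviationError(
                f"attachment marker in '{self.label}' must carry exactly "
                f"one bond")


def get_definition(mol: Molecule, atom_index: int) -> AbbreviationDef:
    """Parse the abbreviation carried by atom *atom_index* (1-based)."""
    from .sketchel import parse_sketchel  # deferred: io depends on model only

    atom = mol.atom(atom_index)
    text = atom.abbreviation_text
    if text is None:
        raise AbbreviationError(f"atom {atom_index} carries no abbreviation")
    d = AbbreviationDef(label=atom.element, fragment=parse_sketchel(text))
    d.validate()
    return d


def set_definition(atom: Atom, fragment: Molecule) -> None:
    """Attach *fragment* (containing one ``*`` marker) to *atom*."""
    from .sketchel import write_sketchel

    AbbreviationDef(label=atom.element, fragment=fragment).validate()
    atom.extensions = [t for t in atom.extensions
                       if not (t.startswith("a") and len(t) > 1)]
    atom.extensions.append("a" + write_sketchel(fragment))


# ---------------------------------------------------------------------------
# splicing


def _transform_points(frag: Molecule, pivot: tuple[float, float],
                      angle: float, target: tuple[float, float]) -> None:
    """Rigid transform in place: rotate about *pivot* then move it to
    *target*."""
    ca, sa = math.cos(angle), math.sin(angle)
    px, py = pivot
    tx, ty = target
    for a in frag.atoms:
        dx, dy = a.x - px, a.y - py
        a.x = tx + dx * ca - dy * sa
        a.y = ty + dx * sa + dy * ca


def splice_fragment(mol: Molecule, placeholder_index: int,
                    fragment: Molecule) -> Molecule:
    """Replace a placeholder atom by *fragment* (one ``*`` marker).

    The single bond from the host to the placeholder (if any) is
    reattached to the fragment's attachment atom, keeping the host bond's
    order, stereo and extensions; the marker is deleted.  The fragment is
    rigid-transformed so the attachment bond has the ideal length and
    extends away from the host.  Shared by abbreviation expansion,
    template enumeration and SAR recomposition.
    """
    placeholder = mol.atom(placeholder_index)
    host_bonds = mol.bonds_of(placeholder_index)
    if len(host_bonds) > 1:
        raise AbbreviationError(
            f"placeholder atom {placeholder_index} has {len(host_bonds)} "
            f"bonds; a terminal fragment allows at most 1")

    frag = fragment.copy()
    markers = [i for i, a in enumerate(frag.atoms, 1)
               if a.element == ATTACHMENT]
    if len(markers) != 1:
        raise AbbreviationError(
            f"fragment has {len(markers)} attachment points; need 1")
    marker = markers[0]
    marker_bonds = frag.bonds_of(marker)
    if len(marker_bonds) != 1:
        raise AbbreviationError("attachment marker must carry exactly one bond")
    attach = marker_bonds[0].other(marker)

    ax, ay = frag.atom(attach).x, frag.atom(attach).y
    mx, my = frag.atom(marker).x, frag.atom(marker).y
    if host_bonds:
        host = host_bonds[0].other(placeholder_index)
        hx, hy = mol.atom(host).x, mol.atom(host).y
        dx, dy = placeholder.x - hx, placeholder.y - hy
        norm = math.hypot(dx, dy) or 1.0
        ux, uy = dx / norm, dy / norm
        target = (hx + IDEAL_BOND * ux, hy + IDEAL_BOND * uy)
        # rotate so the marker direction points back at the host
        cur = math.atan2(my - ay, mx - ax)
        want = math.atan2(hy - target[1], hx - target[0])
        _transform_points(frag, (ax, ay), want - cur, target)
    else:
        _transform_points(frag, (ax, ay), 0.0, (placeholder.x, placeholder.y))

    frag.delete_atom(marker)
    if attach > marker:
        attach -= 1

    out = Molecule()
    index_map: dict[int, int] = {}
    for i, a in enumerate(mol.atoms, 1):
        if i == placeholder_index:
            continue
        index_map[i] = out.add_atom(a.copy())
    frag_map: dict[int, int] = {}
    for i, a in enumerate(frag.atoms, 1):
        frag_map[i] = out.add_atom(a.copy())
    for b in mol.bonds:
        if placeholder_index in (b.from_atom, b.to_atom):
            continue
        nb = b.copy()
        nb.from_atom = index_map[nb.from_atom]
        nb.to_atom = index_map[nb.to_atom]
        out.add_bond(nb)
    if host_bonds:
        hb = host_bonds[0].copy()
        host = hb.other(placeholder_index)
        hb.from_atom = index_map[host]
        hb.to_atom = frag_map[attach]
        out.add_bond(hb)
    for b in frag.bonds:
        nb = b.copy()
        nb.from_atom = frag_map[nb.from_atom]
        nb.to_atom = frag_map[nb.to_atom]
        out.add_bond(nb)
    return out


# ---------------------------------------------------------------------------
# expansion


def expand_one_level(mol: Molecule, atom_index: int) -> Molecule:
    """Expand a single abbreviation placeholder by one level.

    Nested abbreviations inside the fragment remain collapsed.
    """
    d = get_definition(mol, atom_index)
    return splice_fragment(mol, atom_index, d.fragment)


def expand_fully(mol: Molecule,
                 _stack: tuple[str, ...] = ()) -> Molecule:
    """Fixpoint of one-level expansion; no abbreviation tokens remain.

    Raises :class:`CyclicDefinitionError` naming the label chain if a
    definition transitively contains its own label.
    """
    work = mol.copy()
    while True:
        idx = next((i for i, a in enumerate(work.atoms, 1)
                    if a.has_abbreviation), None)
        if idx is None:
            return work
        label = work.atom(idx).element
        if label in _stack:
            raise CyclicDefinitionError(_stack + (label,))
        d = get_definition(work, idx)
        expanded = expand_fully(d.fragment, _stack + (label,))
        work = splice_fragment(work, idx, expanded)


# ---------------------------------------------------------------------------
# subsumption


def subsume_fragment(mol: Molecule, atom_indices: list[int],
                     label: str) -> Molecule:
    """Collapse a connected terminal fragment into one abbreviation node.

    The selection must have at most one bond crossing into the remainder
    (zero means the whole component is abbreviated, in which case the
    attachment marker joins by a zero-order bond so no valence is
    consumed).  One-level expansion of the result restores the original
    formula.
    """
    sel = set(atom_indices)
    if not sel:
        raise AbbreviationError("empty selection")
    for i in sel:
        mol.atom(i)  # bounds check
    # connectivity of the selection
    seen = {min(sel)}
    queue = [min(sel)]
    while queue:
        u = queue.pop()
        for v in mol.neighbours(u):
            if v in sel and v not in seen:
                seen.add(v)
                queue.append(v)
    if seen != sel:
        raise AbbreviationError("selection is not connected")

    crossing = [b for b in mol.bonds
                if (b.from_atom in sel) != (b.to_atom in sel)]
    if len(crossing) > 1:
        raise AbbreviationError(
            f"selection has {len(crossing)} crossing bonds; a terminal "
            f"fragment allows at most 1")

    # build the fragment: selected atoms + marker
    frag = Molecule()
    fmap: dict[int, int] = {}
    for i in sorted(sel):
        fmap[i] = frag.add_atom(mol.atom(i).copy())
    for b in mol.bonds:
        if b.from_atom in sel and b.to_atom in sel:
            nb = b.copy()
            nb.from_atom = fmap[nb.from_atom]
            nb.to_atom = fmap[nb.to_atom]
            frag.add_bond(nb)
    if crossing:
        cb = crossing[0]
        inner = cb.from_atom if cb.from_atom in sel else cb.to_atom
        outer = cb.other(inner)
        marker = frag.add_atom(Atom(ATTACHMENT,
                                    mol.atom(outer).x, mol.atom(outer).y))
        frag.add_bond(Bond(fmap[inner], marker, cb.order))
    else:
        first = min(sel)
        a0 = mol.atom(first)
        marker = frag.add_atom(Atom(ATTACHMENT, a0.x + IDEAL_BOND, a0.y))
        frag.add_bond(Bond(fmap[first], marker, 0))

    cx = sum(mol.atom(i).x for i in sel) / len(sel)
    cy = sum(mol.atom(i).y for i in sel) / len(sel)
    node = Atom(label, cx, cy)
    set_definition(node, frag)

    out = Molecule()
    imap: dict[int, int] = {}
    for i, a in enumerate(mol.atoms, 1):
        if i in sel:
            continue
        imap[i] = out.add_atom(a.copy())
    node_idx = out.add_atom(node)
    for b in mol.bonds:
        if b.from_atom in sel and b.to_atom in sel:
            continue
        nb = b.copy()
        if (nb.from_atom in sel) != (nb.to_atom in sel):
            inner = nb.from_atom if nb.from_atom in sel else nb.to_atom
            outer = nb.other(inner)
            nb.from_atom = imap[outer]
            nb.to_atom = node_idx
        else:
            nb.from_atom = imap[nb.from_atom]
            nb.to_atom = imap[nb.to_atom]
        out.add_bond(nb)
    return out
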