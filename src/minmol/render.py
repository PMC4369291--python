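"""Vector depiction: machine records in, human-readable diagrams out.

Stored 2D coordinates are authoritative — aesthetics belong to the
renderer, not the data.  :func:`layout_fragment` generates fresh
coordinates only for small generated fragments (chains and a single ring
up to 8 atoms) that lack them; anything fancier keeps its original
coordinates.

The renderer produces an intermediate list of drawing primitives (lines,
dashed lines for zero-order bonds, wedge polygons, hash sets, wavy paths
for unknown stereo, text) which is emitted either as deterministic SVG
1.1 text or rasterized to PNG through Pillow at a caller-chosen scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import networkx as nx

from .abbrev import IDEAL_BOND
from .elements import is_element
from .model import Molecule, Stereo


class LayoutUnsupported(ValueError):
    """Raised for topologies outside the small-fragment template set."""


class RenderError(ValueError):
    pass


# ---------------------------------------------------------------------------
# layout


def _graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(1, mol.num_atoms + 1))
    g.add_edges_from((b.from_atom, b.to_atom) for b in mol.bonds)
    return g


def layout_fragment(mol: Molecule) -> Molecule:
    """Return a copy with fresh coordinates: bond lengths exactly 1.5,
    rings on regular polygons, chains zigzagging at 120 degrees.

    Supports trees and molecules with a single ring; fused polycycles
    raise :class:`LayoutUnsupported` so the caller keeps the original
    coordinates.
    """
    out = mol.copy()
    if out.num_atoms == 0:
        return out
    if out.num_atoms == 1:
        out.atoms[0].x = out.atoms[0].y = 0.0
        return out
    g = _graph(out)
    cycles = nx.cycle_basis(g)
    if len(cycles) > 1:
        raise LayoutUnsupported(f"{len(cycles)} rings; at most 1 supported")

    pos: dict[int, tuple[float, float]] = {}
    incoming: dict[int, float] = {}
    if cycles:
        ring = cycles[0]
        n = len(ring)
        radius = IDEAL_BOND / (2.0 * math.sin(math.pi / n))
        for k, idx in enumerate(ring):
            ang = math.pi / 2.0 + 2.0 * math.pi * k / n
            pos[idx] = (radius * math.cos(ang), radius * math.sin(ang))
            # pretend the parent sits at the ring centre
            incoming[idx] = ang
        start_list = list(ring)
    else:
        root = 1
        pos[root] = (0.0, 0.0)
        incoming[root] = 0.0
        start_list = [root]

    queue = list(start_list)
    depth: dict[int, int] = {i: 0 for i in start_list}
    while queue:
        u = queue.pop(0)
        ux, uy = pos[u]
        for v in sorted(g.neighbors(u)):
            if v in pos:
                continue
            ang = _pick_angle(incoming[u], depth[u], pos, (ux, uy))
            pos[v] = (ux + IDEAL_BOND * math.cos(ang),
                      uy + IDEAL_BOND * math.sin(ang))
            incoming[v] = ang
            depth[v] = depth[u] + 1
            queue.append(v)
    # disconnected leftovers: place components side by side
    offset = 0.0
    if pos:
        offset = max(x for x, _ in pos.values()) + 2.0 * IDEAL_BOND
    for i in range(1, out.num_atoms + 1):
        if i not in pos:
            sub = _component_of(g, i)
            sub_mol = _extract(out, sub)
            placed = layout_fragment(sub_mol)
            minx = min((a.x for a in placed.atoms), default=0.0)
            for local, original in enumerate(sub, start=1):
                a = placed.atoms[local - 1]
                pos[original] = (a.x - minx + offset, a.y)
            offset = max(x for x, _ in pos.values()) + 2.0 * IDEAL_BOND
    for i, a in enumerate(out.atoms, 1):
        a.x, a.y = pos[i]
    _assert_distinct(out)
    return out


def _pick_angle(theta_in: float, depth: int,
                pos: dict[int, tuple[float, float]],
                origin: tuple[float, float]) -> float:
    sign = 1.0 if depth % 2 == 0 else -1.0
    prefs = [theta_in + sign * math.radians(60),
             theta_in - sign * math.radians(60),
             theta_in,
             theta_in + math.radians(120),
             theta_in - math.radians(120)]
    prefs += [theta_in + math.radians(30 * k) for k in range(1, 12)]
    ox, oy = origin
    for ang in prefs:
        nx_, ny_ = (ox + IDEAL_BOND * math.cos(ang),
                    oy + IDEAL_BOND * math.sin(ang))
        if all(math.hypot(nx_ - px, ny_ - py) > 0.5
               for px, py in pos.values()):
            return ang
    return prefs[0]


def _component_of(g: nx.Graph, start: int) -> list[int]:
    return sorted(nx.node_connected_component(g, start))


def _extract(mol: Molecule, indices: list[int]) -> Molecule:
    remap = {orig: k for k, orig in enumerate(indices, 1)}
    sub = Molecule()
    for orig in indices:
        sub.add_atom(mol.atom(orig).copy())
    for b in mol.bonds:
        if b.from_atom in remap and b.to_atom in remap:
            nb = b.copy()
            nb.from_atom = remap[nb.from_atom]
            nb.to_atom = remap[nb.to_atom]
            sub.add_bond(nb)
    return sub


def _assert_distinct(mol: Molecule) -> None:
    for i in range(1, mol.num_atoms + 1):
        for j in range(i + 1, mol.num_atoms + 1):
            if mol.distance(i, j) < 1e-6:
                raise LayoutUnsupported(
                    f"layout placed atoms {i} and {j} coincident")


# ---------------------------------------------------------------------------
# primitives


@dataclass
class RenderOptions:
    scale: float = 40.0          # pixels per coordinate unit
    padding: float = 18.0
    font_size: float = 14.0
    scheme: str = "light"        # light | dark
    show_carbon: bool = False    # label every carbon

    @property
    def foreground(self) -> str:
        return "#000000" if self.scheme == "light" else "#ffffff"

    @property
    def background(self) -> str:
        return "#ffffff" if self.scheme == "light" else "#1f1f1f"


@dataclass
class Primitives:
    """Resolution-independent drawing instructions plus extent."""

    ops: list[tuple[Any, ...]] = field(default_factory=list)
    width: float = 0.0
    height: float = 0.0

    def shift(self, dx: float, dy: float) -> None:
        moved: list[tuple[Any, ...]] = []
        for op in self.ops:
            kind = op[0]
            if kind in ("line", "dash"):
                _, x1, y1, x2, y2 = op
                moved.append((kind, x1 + dx, y1 + dy, x2 + dx, y2 + dy))
            elif kind in ("poly", "wavy", "hash"):
                pts = [(x + dx, y + dy) for x, y in op[1]]
                moved.append((kind, pts))
            elif kind == "text":
                _, x, y, s, size = op
                moved.append((kind, x + dx, y + dy, s, size))
        self.ops = moved


def _label_for(atom) -> Optional[str]:
    if atom.element != "C":
        return atom.element
    if atom.charge or atom.isotope or atom.has_abbreviation:
        return atom.element
    return None


def molecule_primitives(mol: Molecule, options: RenderOptions) -> Primitives:
    if mol.num_atoms and all(a.x == 0.0 and a.y == 0.0 for a in mol.atoms) \
            and mol.num_atoms > 1:
        raise RenderError("molecule has no 2D coordinates; run "
                          "layout_fragment first")
    s, pad = options.scale, options.padding
    xs = [a.x for a in mol.atoms] or [0.0]
    ys = [a.y for a in mol.atoms] or [0.0]
    minx, maxx, miny, maxy = min(xs), max(xs), min(ys), max(ys)

    def px(x: float, y: float) -> tuple[float, float]:
        return ((x - minx) * s + pad, (maxy - y) * s + pad)

    prims = Primitives(width=(maxx - minx) * s + 2 * pad,
                       height=(maxy - miny) * s + 2 * pad)
    labelled = {i: _label_for(a) is not None or options.show_carbon
                for i, a in enumerate(mol.atoms, 1)}

    for b in mol.bonds:
        x1, y1 = px(mol.atom(b.from_atom).x, mol.atom(b.from_atom).y)
        x2, y2 = px(mol.atom(b.to_atom).x, mol.atom(b.to_atom).y)
        # leave a gap around drawn labels
        gap = 0.30 * options.font_size
        dx, dy = x2 - x1, y2 - y1
        length = math.hypot(dx, dy) or 1.0
        ux, uy = dx / length, dy / length
        if labelled[b.from_atom]:
            x1, y1 = x1 + ux * gap, y1 + uy * gap
        if labelled[b.to_atom]:
            x2, y2 = x2 - ux * gap, y2 - uy * gap
        nxv, nyv = -uy, ux  # unit normal
        if b.order == 0:
            prims.ops.append(("dash", x1, y1, x2, y2))
        elif b.stereo is Stereo.INCLINED:
            w = 0.14 * s
            prims.ops.append(("poly", [(x1, y1),
                                       (x2 + nxv * w, y2 + nyv * w),
                                       (x2 - nxv * w, y2 - nyv * w)]))
        elif b.stereo is Stereo.DECLINED:
            pts: list[tuple[float, float]] = []
            nseg = 6
            for k in range(nseg + 1):
                t = k / nseg
                w = 0.14 * s * t
                mx_, my_ = x1 + (x2 - x1) * t, y1 + (y2 - y1) * t
                pts.append((mx_ + nxv * w, my_ + nyv * w))
                pts.append((mx_ - nxv * w, my_ - nyv * w))
            prims.ops.append(("hash", pts))
        elif b.stereo is Stereo.UNKNOWN:
            pts = []
            nseg = 8
            for k in range(nseg + 1):
                t = k / nseg
                w = 0.10 * s * math.sin(t * math.pi * 4)
                mx_, my_ = x1 + (x2 - x1) * t, y1 + (y2 - y1) * t
                pts.append((mx_ + nxv * w, my_ + nyv * w))
            prims.ops.append(("wavy", pts))
        else:
            offsets = {1: [0.0], 2: [0.07 * s, -0.07 * s],
                       3: [0.0, 0.12 * s, -0.12 * s],
                       4: [0.05 * s, -0.05 * s, 0.15 * s, -0.15 * s],
                       5: [0.0, 0.10 * s, -0.10 * s, 0.20 * s, -0.20 * s]}
            for off in offsets.get(b.order, [0.0]):
                prims.ops.append(("line",
                                  x1 + nxv * off, y1 + nyv * off,
                                  x2 + nxv * off, y2 + nyv * off))

    for i, a in enumerate(mol.atoms, 1):
        label = _label_for(a) or ("C" if options.show_carbon else None)
        if label is None and not mol.bonds_of(i):
            label = a.element  # lone atoms always get their symbol
        if label is None:
            continue
        x, y = px(a.x, a.y)
        prims.ops.append(("text", x, y, label, options.font_size))
        sup_x = x + 0.42 * options.font_size * max(1, len(label))
        sup_y = y - 0.45 * options.font_size
        if a.isotope:
            prims.ops.append(("text", x - 0.55 * options.font_size, sup_y,
                              str(a.isotope), 0.7 * options.font_size))
        if a.charge:
            mag = abs(a.charge)
            sign = "+" if a.charge > 0 else "−"
            prims.ops.append(("text", sup_x, sup_y,
                              (str(mag) if mag > 1 else "") + sign,
                              0.7 * options.font_size))
    return prims


# ---------------------------------------------------------------------------
# SVG


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _svg_body(prims: Primitives, options: RenderOptions) -> list[str]:
    fg = options.foreground
    out: list[str] = []
    for op in prims.ops:
        kind = op[0]
        if kind == "line":
            _, x1, y1, x2, y2 = op
            out.append(f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
                       f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
                       f'stroke="{fg}" stroke-width="1.6" '
                       f'stroke-linecap="round"/>')
        elif kind == "dash":
            _, x1, y1, x2, y2 = op
            out.append(f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
                       f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
                       f'stroke="{fg}" stroke-width="1.6" '
                       f'stroke-dasharray="4,3"/>')
        elif kind == "poly":
            pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in op[1])
            out.append(f'<polygon points="{pts}" fill="{fg}"/>')
        elif kind == "hash":
            pts = op[1]
            segs = []
            for k in range(0, len(pts) - 1, 2):
                (xa, ya), (xb, yb) = pts[k], pts[k + 1]
                segs.append(f'<line x1="{_fmt(xa)}" y1="{_fmt(ya)}" '
                            f'x2="{_fmt(xb)}" y2="{_fmt(yb)}" '
                            f'stroke="{fg}" stroke-width="1.3"/>')
            out.append('<g class="hash">' + "".join(segs) + "</g>")
        elif kind == "wavy":
            pts = op[1]
            d = f"M {_fmt(pts[0][0])} {_fmt(pts[0][1])} " + " ".join(
                f"L {_fmt(x)} {_fmt(y)}" for x, y in pts[1:])
            out.append(f'<path d="{d}" fill="none" stroke="{fg}" '
                       f'stroke-width="1.6"/>')
        elif kind == "text":
            _, x, y, s, size = op
            out.append(f'<text x="{_fmt(x)}" y="{_fmt(y)}" '
                       f'font-family="Helvetica,Arial,sans-serif" '
                       f'font-size="{_fmt(size)}" fill="{fg}" '
                       f'text-anchor="middle" dominant-baseline="central"'
                       f'>{_xml_escape(s)}</text>')
    return out


def _xml_escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;")
             .replace(">", "&gt;"))


def _svg_document(prims: Primitives, options: RenderOptions) -> str:
    w, h = _fmt(prims.width), _fmt(prims.height)
    lines = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" '
             f'height="{h}" viewBox="0 0 {w} {h}">',
             f'<rect width="{w}" height="{h}" '
             f'fill="{options.background}"/>']
    lines.extend(_svg_body(prims, options))
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def render_molecule_svg(mol: Molecule,
                        options: RenderOptions | None = None) -> str:
    """Pure-vector SVG; deterministic for equal inputs."""
    options = options or RenderOptions()
    return _svg_document(molecule_primitives(mol, options), options)


def render_molecule_png(mol: Molecule,
                        options: RenderOptions | None = None) -> bytes:
    """Convenience raster of the same primitives (resolution = scale)."""
    options = options or RenderOptions()
    return _rasterize(molecule_primitives(mol, options), options)


def _rasterize(prims: Primitives, options: RenderOptions) -> bytes:
    import io

    from PIL import Image, ImageDraw

    w = max(1, int(math.ceil(prims.width)))
    h = max(1, int(math.ceil(prims.height)))
    img = Image.new("RGB", (w, h), options.background)
    draw = ImageDraw.Draw(img)
    fg = options.foreground
    for op in prims.ops:
        kind = op[0]
        if kind == "line":
            draw.line(op[1:5], fill=fg, width=2)
        elif kind == "dash":
            x1, y1, x2, y2 = op[1:5]
            steps = max(2, int(math.hypot(x2 - x1, y2 - y1) / 7))
            for k in range(steps):
                t0, t1 = k / steps, (k + 0.55) / steps
                draw.line((x1 + (x2 - x1) * t0, y1 + (y2 - y1) * t0,
                           x1 + (x2 - x1) * t1, y1 + (y2 - y1) * t1),
                          fill=fg, width=2)
        elif kind == "poly":
            draw.polygon(op[1], fill=fg)
        elif kind == "hash":
            pts = op[1]
            for k in range(0, len(pts) - 1, 2):
                draw.line((*pts[k], *pts[k + 1]), fill=fg, width=1)
        elif kind == "wavy":
            draw.line([c for p in op[1] for c in p], fill=fg, width=2)
        elif kind == "text":
            _, x, y, s, size = op
            draw.text((x, y), s, fill=fg, anchor="mm")
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# reaction schemes


def render_reaction_svg(steps, options: RenderOptions | None = None) -> str:
    """Render steps from ``assemble_reaction_scheme`` as one SVG.

    Reactants sit left of the arrow joined by plus signs, products right,
    reagents above the arrow; multiple steps stack vertically in a single
    coordinate system.
    """
    options = options or RenderOptions()
    if not steps or all(not step for step in steps):
        raise RenderError("empty reaction scheme")
    gap = 14.0
    arrow_len = 2.2 * options.scale
    rows: list[Primitives] = []
    for step in steps:
        reactants = [c for c in step if c.role == "reactant"]
        reagents = [c for c in step if c.role == "reagent"]
        products = [c for c in step if c.role == "product"]
        row = Primitives()
        x = 0.0
        mid_guess = 0.0

        def comp_prims(comp) -> Primitives:
            if isinstance(comp.value, Molecule):
                p = molecule_primitives(comp.value, options)
            else:
                text = "?" if comp.value is None else str(comp.value)
                p = Primitives(width=options.font_size * (len(text) * 0.7 + 1),
                               height=options.font_size * 2)
                p.ops.append(("text", p.width / 2, p.height / 2, text,
                              options.font_size))
            if comp.quantity is not None:
                p.ops.append(("text", p.width / 2, p.height + 2,
                              str(comp.quantity), 0.8 * options.font_size))
                p.height += options.font_size
            return p

        heights: list[float] = []
        parts: list[tuple[float, Primitives | str]] = []
        for k, comp in enumerate(reactants):
            if k:
                parts.append((x, "+"))
                x += gap + options.font_size
            p = comp_prims(comp)
            parts.append((x, p))
            heights.append(p.height)
            x += p.width + gap
        arrow_x = x
        x += arrow_len + gap
        for k, comp in enumerate(products):
            if k:
                parts.append((x, "+"))
                x += gap + options.font_size
            p = comp_prims(comp)
            parts.append((x, p))
            heights.append(p.height)
            x += p.width + gap
        reagent_h = options.font_size * 1.4 * max(1, len(reagents))
        row_h = max(heights or [options.scale]) + reagent_h
        mid_y = reagent_h + max(heights or [options.scale]) / 2.0
        for px_, item in parts:
            if item == "+":
                row.ops.append(("text", px_ + options.font_size / 2, mid_y,
                                "+", options.font_size))
            else:
                item.shift(px_, mid_y - item.height / 2)
                row.ops.extend(item.ops)
        # arrow
        ay = mid_y
        row.ops.append(("line", arrow_x, ay, arrow_x + arrow_len, ay))
        row.ops.append(("poly", [(arrow_x + arrow_len, ay),
                                 (arrow_x + arrow_len - 7, ay - 4),
                                 (arrow_x + arrow_len - 7, ay + 4)]))
        for k, comp in enumerate(reagents):
            label = (comp.value if not isinstance(comp.value, Molecule)
                     else comp.column)
            row.ops.append(("text", arrow_x + arrow_len / 2,
                            ay - (k + 1) * options.font_size * 1.2,
                            "?" if label is None else str(label),
                            0.85 * options.font_size))
        row.width = x
        row.height = row_h
        rows.append(row)
        mid_guess = max(mid_guess, x)

    total = Primitives(width=max(r.width for r in rows) + 2 * options.padding)
    y = options.padding
    for r in rows:
        r.shift(options.padding, y)
        total.ops.extend(r.ops)
        y += r.height + 2 * gap
    total.height = y - 2 * gap + options.padding
    return _svg_document(total, options)
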