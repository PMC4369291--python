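r"""Line-oriented molecule serialization with the compatibility contract.

The grammar is deliberately small and frozen by the golden files under
``tests/golden/``.  A document is UTF-8 text:

.. code-block:: none

    minmol 1 <natoms> <nbonds>
    <atom line> x natoms
    <bond line> x nbonds
    end minmol

Fields within a line are TAB-separated; TAB, newline, carriage return and
backslash inside a field are escaped as ``\t``, ``\n``, ``\r`` and ``\\``.

Atom line fields, in order: element token, x, y (4 decimal places),
charge, unpaired count, virtual hydrogens (``.`` for automatic, otherwise
an explicit non-negative integer), then zero or more extension tokens,
one field each.  Bond line fields: from index, to index (1-based), order,
stereo code (``F``/``I``/``D``/``U``), then extension tokens.

Extension tokens are preserved verbatim and in order whether or not their
reserved prefix is understood — read/modify/write never destroys
information a future (or past) implementation may care about.
Abbreviation tokens (`a` prefix) carry a complete nested document as
their payload; the field escaping handles the nesting.

Files use the ``.el`` extension and the ``chemical/x-sketchel`` MIME type.
"""

from __future__ import annotations

from .model import AUTO, Atom, Bond, Molecule, Stereo, check_graph

MIME_TYPE = "chemical/x-sketchel"
FILE_EXTENSION = ".el"

_MAGIC = "minmol"
_VERSION = "1"


class SketchelError(ValueError):
    """Parse or write failure; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _escape(s: str) -> str:
    return (s.replace("\\", "\\\\").replace("\t", "\\t")
             .replace("\n", "\\n").replace("\r", "\\r"))


def _unescape(s: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "\\" and i + 1 < len(s):
            nxt = s[i + 1]
            out.append({"t": "\t", "n": "\n", "r": "\r", "\\": "\\"}
                       .get(nxt, nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _int_field(raw: str, what: str, line: int) -> int:
    try:
        return int(raw)
    except ValueError:
        raise SketchelError(f"non-integer {what}: {raw!r}", line) from None


def _float_field(raw: str, what: str, line: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise SketchelError(f"non-numeric {what}: {raw!r}", line) from None


def parse_sketchel(text: str) -> Molecule:
    """Parse a document into a :class:`Molecule`.

    Every extension token, known or unknown, is preserved in order.
    """
    lines = text.splitlines()
    if not lines:
        raise SketchelError("empty document", 1)
    header = lines[0].split(" ")
    if len(header) != 4 or header[0] != _MAGIC:
        raise SketchelError(f"malformed header: {lines[0]!r}", 1)
    if header[1] != _VERSION:
        raise SketchelError(f"unsupported version {header[1]!r}", 1)
    natoms = _int_field(header[2], "atom count", 1)
    nbonds = _int_field(header[3], "bond count", 1)
    expected = 1 + natoms + nbonds + 1
    if len(lines) < expected:
        raise SketchelError(
            f"document has {len(lines)} lines; {expected} required by the "
            f"header counts", len(lines))

    mol = Molecule()
    for k in range(natoms):
        ln = 2 + k
        fields = lines[1 + k].split("\t")
        if len(fields) < 6:
            raise SketchelError(
                f"atom line has {len(fields)} fields; at least 6 required", ln)
        element = _unescape(fields[0])
        if not element:
            raise SketchelError("empty element token", ln)
        x = _float_field(fields[1], "x coordinate", ln)
        y = _float_field(fields[2], "y coordinate", ln)
        charge = _int_field(fields[3], "charge", ln)
        unpaired = _int_field(fields[4], "unpaired count", ln)
        if unpaired < 0:
            raise SketchelError(f"negative unpaired count {unpaired}", ln)
        if fields[5] == ".":
            vh = AUTO
        else:
            vh = _int_field(fields[5], "virtual hydrogen count", ln)
            if vh < 0:
                raise SketchelError(f"negative hydrogen count {vh}", ln)
        exts = [_unescape(f) for f in fields[6:]]
        mol.add_atom(Atom(element, x, y, charge, unpaired, vh, exts))

    stereo_codes = {s.value: s for s in Stereo}
    for k in range(nbonds):
        ln = 1 + natoms + 1 + k
        fields = lines[natoms + 1 + k].split("\t")
        if len(fields) < 4:
            raise SketchelError(
                f"bond line has {len(fields)} fields; at least 4 required", ln)
        fr = _int_field(fields[0], "from index", ln)
        to = _int_field(fields[1], "to index", ln)
        order = _int_field(fields[2], "bond order", ln)
        code = fields[3]
        if code not in stereo_codes:
            raise SketchelError(f"unknown stereo code {code!r}", ln)
        exts = [_unescape(f) for f in fields[4:]]
        mol.add_bond(Bond(fr, to, order, stereo_codes[code], exts))

    term_ln = 1 + natoms + nbonds
    if lines[term_ln] != f"end {_MAGIC}":
        raise SketchelError(f"missing terminator, got {lines[term_ln]!r}",
                            term_ln + 1)
    return mol


def write_sketchel(mol: Molecule) -> str:
    """Serialize; byte-stable for value-equal inputs.

    Refuses molecules that violate the structural invariants.
    """
    viols = check_graph(mol)
    if viols:
        raise SketchelError(f"refusing to write invalid molecule: {viols[0]}")
    out: list[str] = [f"{_MAGIC} {_VERSION} {mol.num_atoms} {mol.num_bonds}"]
    for a in mol.atoms:
        vh = "." if a.virtual_hydrogens is None else str(a.virtual_hydrogens)
        fields = [_escape(a.element), f"{a.x:.4f}", f"{a.y:.4f}",
                  str(a.charge), str(a.unpaired), vh]
        fields.extend(_escape(t) for t in a.extensions)
        out.append("\t".join(fields))
    for b in mol.bonds:
        fields = [str(b.from_atom), str(b.to_atom), str(b.order),
                  b.stereo.value]
        fields.extend(_escape(t) for t in b.extensions)
        out.append("\t".join(fields))
    out.append(f"end {_MAGIC}")
    return "\n".join(out) + "\n"
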