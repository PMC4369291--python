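"""Typed tabular container with tolerant header "aspects".

A datasheet is a strongly typed table — each column is one of *molecule*,
*string*, *integer*, *real* or *boolean* — serialized as XML with
molecule cells embedding the molecule serialization as escaped text.

The header carries ordered extensions (name + opaque payload).
Extensions following a recognized protocol are *aspects*: Solvent,
SARTable, Reaction, Experiment.  The contract is tolerance: software that
does not recognize an aspect can still load, edit cells, add or delete
rows and rewrite the sheet without destroying the higher-order markup,
and an aware application repairs a damaged aspect (a deleted required
column is recreated with default values) rather than failing.

Aspect payloads here are JSON; the exact field lists are repo-defined
(minimal sets satisfying the tolerance contract) and frozen by golden
files.
"""

from __future__ import annotations

import enum
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any, Optional

from .abbrev import splice_fragment
from .formula import STRICT, HydrogenMode
from .model import Molecule
from .molfile import parse_sdfile, write_sd_record
from .sketchel import parse_sketchel, write_sketchel

log = logging.getLogger(__name__)

FILE_EXTENSION = ".ds"


class DataSheetError(ValueError):
    pass


class ColumnType(enum.Enum):
    MOLECULE = "molecule"
    STRING = "string"
    INTEGER = "integer"
    REAL = "real"
    BOOLEAN = "boolean"


_PYTYPES = {
    ColumnType.MOLECULE: Molecule,
    ColumnType.STRING: str,
    ColumnType.INTEGER: int,
    ColumnType.REAL: (int, float),
    ColumnType.BOOLEAN: bool,
}


@dataclass
class Column:
    name: str
    type: ColumnType


@dataclass
class Extension:
    """A named header extension; payload is opaque text, preserved verbatim."""

    name: str
    payload: str


@dataclass
class DataSheet:
    columns: list[Column] = field(default_factory=list)
    rows: list[list[Any]] = field(default_factory=list)
    header_extensions: list[Extension] = field(default_factory=list)

    # -- columns ---------------------------------------------------------

    def column_index(self, name: str) -> int:
        for i, c in enumerate(self.columns):
            if c.name == name:
                return i
        raise DataSheetError(f"no column named {name!r}")

    def has_column(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    def append_column(self, name: str, ctype: ColumnType) -> None:
        if self.has_column(name):
            raise DataSheetError(f"duplicate column name {name!r}")
        self.columns.append(Column(name, ctype))
        for row in self.rows:
            row.append(None)

    def delete_column(self, name: str) -> None:
        i = self.column_index(name)
        self.columns.pop(i)
        for row in self.rows:
            row.pop(i)

    # -- cells -----------------------------------------------------------

    def append_row(self, cells: Optional[list[Any]] = None) -> int:
        row = [None] * len(self.columns)
        self.rows.append(row)
        if cells is not None:
            for i, v in enumerate(cells):
                self.set_cell(len(self.rows) - 1, self.columns[i].name, v)
        return len(self.rows) - 1

    def delete_row(self, index: int) -> None:
        self.rows.pop(index)

    def get_cell(self, row: int, column: str) -> Any:
        return self.rows[row][self.column_index(column)]

    def set_cell(self, row: int, column: str, value: Any) -> None:
        i = self.column_index(column)
        if value is not None:
            expected = _PYTYPES[self.columns[i].type]
            if (not isinstance(value, expected)
                    or (self.columns[i].type is ColumnType.INTEGER
                        and isinstance(value, bool))):
                raise DataSheetError(
                    f"row {row}, column {column!r}: value {value!r} does not "
                    f"conform to type {self.columns[i].type.value}")
        self.rows[row][i] = value

    # -- aspects ---------------------------------------------------------

    def extension(self, name: str) -> Optional[Extension]:
        for e in self.header_extensions:
            if e.name == name:
                return e
        return None

    def aspect(self, name: str) -> "Aspect":
        ext = self.extension(name)
        if ext is None or name not in ASPECT_TYPES:
            raise DataSheetError(f"aspect {name!r} not present")
        return ASPECT_TYPES[name].from_payload(ext.payload)

    @property
    def aspects(self) -> dict[str, "Aspect"]:
        out: dict[str, Aspect] = {}
        for e in self.header_extensions:
            if e.name in ASPECT_TYPES:
                out[e.name] = ASPECT_TYPES[e.name].from_payload(e.payload)
        return out

    def copy(self) -> "DataSheet":
        sheet = DataSheet(
            [Column(c.name, c.type) for c in self.columns],
            [[(v.copy() if isinstance(v, Molecule) else v) for v in row]
             for row in self.rows],
            [Extension(e.name, e.payload) for e in self.header_extensions])
        return sheet

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataSheet):
            return NotImplemented
        return (self.columns == other.columns
                and self.header_extensions == other.header_extensions
                and self.rows == other.rows)


# ---------------------------------------------------------------------------
# aspects


class Aspect:
    """Base for typed views over recognized header extensions."""

    name: str = ""

    @classmethod
    def from_payload(cls, payload: str) -> "Aspect":
        raise NotImplementedError

    def to_payload(self) -> str:
        raise NotImplementedError

    def required_columns(self) -> list[Column]:
        """Columns the aspect needs; recreated with defaults on repair."""
        raise NotImplementedError


@dataclass
class SolventColumn:
    column: str
    role: str = ""
    units: str = ""
    type: str = "string"


@dataclass
class SolventAspect(Aspect):
    """Display roles and default units for physical-property columns.

    Purely suggestive: carried and rendered, never enforced or computed.
    """

    name = "Solvent"
    columns: list[SolventColumn] = field(default_factory=list)

    @classmethod
    def from_payload(cls, payload: str) -> "SolventAspect":
        data = json.loads(payload) if payload.strip() else {}
        return cls([SolventColumn(c.get("column", ""), c.get("role", ""),
                                  c.get("units", ""), c.get("type", "string"))
                    for c in data.get("columns", [])])

    def to_payload(self) -> str:
        return json.dumps({"columns": [
            {"column": c.column, "role": c.role, "units": c.units,
             "type": c.type} for c in self.columns]}, indent=1)

    def required_columns(self) -> list[Column]:
        return [Column(c.column, ColumnType(c.type)) for c in self.columns]


@dataclass
class PropertyColumn:
    column: str
    units: str = ""
    vmin: Optional[float] = None
    vmax: Optional[float] = None


@dataclass
class SARTableAspect(Aspect):
    """Scaffold/substituent/composite layout for SAR tables."""

    name = "SARTable"
    scaffold: str = "Scaffold"
    substituents: list[str] = field(default_factory=list)
    molecule: str = "Molecule"
    properties: list[PropertyColumn] = field(default_factory=list)

    @classmethod
    def from_payload(cls, payload: str) -> "SARTableAspect":
        d = json.loads(payload) if payload.strip() else {}
        return cls(d.get("scaffold", "Scaffold"),
                   list(d.get("substituents", [])),
                   d.get("molecule", "Molecule"),
                   [PropertyColumn(p.get("column", ""), p.get("units", ""),
                                   p.get("min"), p.get("max"))
                    for p in d.get("properties", [])])

    def to_payload(self) -> str:
        return json.dumps({
            "scaffold": self.scaffold,
            "substituents": self.substituents,
            "molecule": self.molecule,
            "properties": [{"column": p.column, "units": p.units,
                            "min": p.vmin, "max": p.vmax}
                           for p in self.properties]}, indent=1)

    def required_columns(self) -> list[Column]:
        cols = [Column(self.scaffold, ColumnType.MOLECULE)]
        cols += [Column(s, ColumnType.MOLECULE) for s in self.substituents]
        cols.append(Column(self.molecule, ColumnType.MOLECULE))
        cols += [Column(p.column, ColumnType.REAL) for p in self.properties]
        return cols


@dataclass
class ReactionStep:
    reactants: list[str] = field(default_factory=list)
    reagents: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)


@dataclass
class ReactionAspect(Aspect):
    """Groups molecule/text/number columns into one reaction step."""

    name = "Reaction"
    steps: list[ReactionStep] = field(default_factory=list)
    # component column -> quantity column (Experiment only)
    quantities: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_payload(cls, payload: str) -> "ReactionAspect":
        d = json.loads(payload) if payload.strip() else {}
        return cls([ReactionStep(list(s.get("reactants", [])),
                                 list(s.get("reagents", [])),
                                 list(s.get("products", [])))
                    for s in d.get("steps", [])],
                   dict(d.get("quantities", {})))

    def to_payload(self) -> str:
        body: dict[str, Any] = {"steps": [
            {"reactants": s.reactants, "reagents": s.reagents,
             "products": s.products} for s in self.steps]}
        if self.quantities:
            body["quantities"] = self.quantities
        return json.dumps(body, indent=1)

    def required_columns(self) -> list[Column]:
        cols: list[Column] = []
        seen: set[str] = set()
        for s in self.steps:
            for name in s.reactants + s.reagents + s.products:
                if name not in seen:
                    seen.add(name)
                    cols.append(Column(name, ColumnType.MOLECULE))
        for qcol in self.quantities.values():
            if qcol not in seen:
                seen.add(qcol)
                cols.append(Column(qcol, ColumnType.REAL))
        return cols


@dataclass
class ExperimentAspect(ReactionAspect):
    """Reaction plus quantities; allows multiple steps."""

    name = "Experiment"

    @classmethod
    def from_payload(cls, payload: str) -> "ExperimentAspect":
        base = ReactionAspect.from_payload(payload)
        return cls(base.steps, base.quantities)


ASPECT_TYPES: dict[str, type[Aspect]] = {
    "Solvent": SolventAspect,
    "SARTable": SARTableAspect,
    "Reaction": ReactionAspect,
    "Experiment": ExperimentAspect,
}


# ---------------------------------------------------------------------------
# XML serialization


def parse_datasheet(xml_text: str) -> DataSheet:
    """Parse the datasheet XML; unknown aspects stay opaque payloads."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as e:
        raise DataSheetError(f"malformed XML: {e}") from None
    if root.tag != "DataSheet":
        raise DataSheetError(f"unexpected root element {root.tag!r}")
    sheet = DataSheet()
    header = root.find("Header")
    if header is None:
        raise DataSheetError("missing Header element")
    for el in header:
        if el.tag == "Column":
            name = el.get("name", "")
            try:
                ctype = ColumnType(el.get("type", ""))
            except ValueError:
                raise DataSheetError(
                    f"column {name!r}: unknown type {el.get('type')!r}"
                ) from None
            if sheet.has_column(name):
                raise DataSheetError(f"duplicate column name {name!r}")
            sheet.columns.append(Column(name, ctype))
        elif el.tag == "Extension":
            sheet.header_extensions.append(
                Extension(el.get("name", ""), el.text or ""))
    rows_el = root.find("Rows")
    for r, row_el in enumerate(rows_el if rows_el is not None else []):
        idx = sheet.append_row()
        for cell_el in row_el:
            cname = cell_el.get("column", "")
            if not sheet.has_column(cname):
                raise DataSheetError(
                    f"row {r}, cell references unknown column {cname!r}")
            text = cell_el.text or ""
            sheet.rows[idx][sheet.column_index(cname)] = _cell_from_text(
                text, sheet.columns[sheet.column_index(cname)].type, r, cname)
    return sheet


def _cell_from_text(text: str, ctype: ColumnType, row: int, col: str) -> Any:
    try:
        if ctype is ColumnType.MOLECULE:
            return parse_sketchel(text)
        if ctype is ColumnType.STRING:
            return text
        if ctype is ColumnType.INTEGER:
            return int(text)
        if ctype is ColumnType.REAL:
            return float(text)
        if ctype is ColumnType.BOOLEAN:
            if text not in ("true", "false"):
                raise ValueError(text)
            return text == "true"
    except ValueError as e:
        raise DataSheetError(
            f"row {row}, column {col!r}: cell {text!r} does not parse as "
            f"{ctype.value} ({e})") from None
    raise AssertionError(ctype)


def _cell_to_text(value: Any, ctype: ColumnType) -> str:
    if ctype is ColumnType.MOLECULE:
        return write_sketchel(value)
    if ctype is ColumnType.BOOLEAN:
        return "true" if value else "false"
    if ctype is ColumnType.REAL:
        return repr(float(value))
    return str(value)


def write_datasheet(sheet: DataSheet) -> str:
    """Serialize to XML; parse ∘ write is the identity, and unknown
    extension payloads survive byte-identically."""
    root = ET.Element("DataSheet")
    header = ET.SubElement(root, "Header")
    for c in sheet.columns:
        ET.SubElement(header, "Column", name=c.name, type=c.type.value)
    for e in sheet.header_extensions:
        ext = ET.SubElement(header, "Extension", name=e.name)
        ext.text = e.payload
    rows_el = ET.SubElement(root, "Rows")
    for row in sheet.rows:
        row_el = ET.SubElement(rows_el, "Row")
        for c, value in zip(sheet.columns, row):
            if value is None:
                continue  # null cells are absent elements, not empty strings
            cell = ET.SubElement(row_el, "Cell", column=c.name)
            cell.text = _cell_to_text(value, c.type)
    return ET.tostring(root, encoding="unicode") + "\n"


# ---------------------------------------------------------------------------
# aspect repair and use


def repair_aspect(sheet: DataSheet, aspect_name: str) -> DataSheet:
    """Recreate missing aspect-required columns with default (null) values.

    Existing data is untouched; the operation is idempotent.
    """
    if aspect_name not in ASPECT_TYPES:
        raise DataSheetError(f"unknown aspect {aspect_name!r}")
    aspect = sheet.aspect(aspect_name)
    out = sheet.copy()
    for col in aspect.required_columns():
        if not out.has_column(col.name):
            log.info("aspect %s: recreating missing column %r",
                     aspect_name, col.name)
            out.append_column(col.name, col.type)
    return out


def compose_sar_molecule(scaffold: Molecule,
                         substituents: dict[str, Molecule]) -> Molecule:
    """Graft substituent fragments onto scaffold placeholders (R1, R2, …).

    Matching is by exact label; every placeholder must have a fragment
    and each fragment exactly one attachment marker.  Extra entries in
    *substituents* that match no placeholder are ignored with a warning.
    """
    from .validate import is_placeholder  # shared placeholder grammar

    work = scaffold.copy()
    used: set[str] = set()
    while True:
        idx = next((i for i, a in enumerate(work.atoms, 1)
                    if a.element in substituents
                    and not a.has_abbreviation), None)
        if idx is None:
            break
        label = work.atom(idx).element
        used.add(label)
        work = splice_fragment(work, idx, substituents[label])
    for i, a in enumerate(work.atoms, 1):
        if is_placeholder(a.element) and not a.has_abbreviation:
            raise DataSheetError(
                f"atom {i}: placeholder {a.element!r} has no substituent")
    for label in substituents:
        if label not in used:
            log.warning("substituent %r matches no scaffold placeholder",
                        label)
    return work


@dataclass
class ReactionComponent:
    role: str           # reactant | reagent | product
    column: str
    value: Any          # Molecule, text or number (None if cell empty)
    quantity: Any = None


def assemble_reaction_scheme(sheet: DataSheet, row: int,
                             ) -> list[list[ReactionComponent]]:
    """Group a row's cells into per-step ordered component lists.

    Requires the Reaction or Experiment aspect; raises otherwise.
    """
    aspect: Optional[ReactionAspect] = None
    for name in ("Experiment", "Reaction"):
        if sheet.extension(name) is not None:
            aspect = sheet.aspect(name)  # type: ignore[assignment]
            break
    if aspect is None:
        raise DataSheetError("sheet carries no Reaction or Experiment aspect")
    steps: list[list[ReactionComponent]] = []
    for s in aspect.steps:
        comps: list[ReactionComponent] = []
        for role, names in (("reactant", s.reactants),
                            ("reagent", s.reagents),
                            ("product", s.products)):
            for cname in names:
                value = (sheet.get_cell(row, cname)
                         if sheet.has_column(cname) else None)
                qty = None
                qcol = aspect.quantities.get(cname)
                if qcol and sheet.has_column(qcol):
                    qty = sheet.get_cell(row, qcol)
                comps.append(ReactionComponent(role, cname, value, qty))
        steps.append(comps)
    return steps


# ---------------------------------------------------------------------------
# SDfile bridge


def export_sdfile(sheet: DataSheet, molecule_column: str) -> str:
    """One SD record per row; other columns become ``> <name>`` fields.

    Column typing and aspects do not survive this conversion; the losses
    are logged.
    """
    ci = sheet.column_index(molecule_column)
    if sheet.columns[ci].type is not ColumnType.MOLECULE:
        raise DataSheetError(
            f"column {molecule_column!r} has type "
            f"{sheet.columns[ci].type.value}, not molecule")
    for c in sheet.columns:
        if c.name != molecule_column and c.type is not ColumnType.STRING:
            log.info("SD export: column %r loses its %s typing",
                     c.name, c.type.value)
    for e in sheet.header_extensions:
        log.info("SD export: header extension %r dropped", e.name)
    out: list[str] = []
    for r, row in enumerate(sheet.rows):
        mol = row[ci]
        if mol is None:
            log.info("SD export: row %d has no molecule; skipped", r)
            continue
        fields: dict[str, str] = {}
        for c, value in zip(sheet.columns, row):
            if c.name == molecule_column or value is None:
                continue
            if c.type is ColumnType.MOLECULE:
                log.info("SD export: secondary molecule column %r rendered "
                         "as text", c.name)
                fields[c.name] = write_sketchel(value)
            else:
                fields[c.name] = _cell_to_text(value, c.type)
        record, loss = write_sd_record(mol, fields)
        for entry in loss.entries:
            log.info("SD export row %d: %s", r, entry)
        out.append(record)
    return "".join(out)


def sdfile_to_datasheet(text: str,
                        hydrogen_mode: HydrogenMode = STRICT) -> DataSheet:
    """Import an SDfile: molecule column plus best-effort typed fields.

    Field types are sniffed integer → real → string; anything else
    (including booleans, which SD data cannot distinguish from text)
    falls back to string.
    """
    records = parse_sdfile(text, hydrogen_mode)
    sheet = DataSheet()
    sheet.columns.append(Column("Molecule", ColumnType.MOLECULE))
    names: list[str] = []
    for _, fields, _ in records:
        for name in fields:
            if name not in names:
                names.append(name)
    types: dict[str, ColumnType] = {}
    for name in names:
        values = [f[name] for _, f, _ in records if name in f]
        types[name] = _sniff_type(values)
        sheet.columns.append(Column(name, types[name]))
    for mol, fields, _ in records:
        idx = sheet.append_row()
        sheet.rows[idx][0] = mol
        for name, raw in fields.items():
            ci = sheet.column_index(name)
            if types[name] is ColumnType.INTEGER:
                sheet.rows[idx][ci] = int(raw)
            elif types[name] is ColumnType.REAL:
                sheet.rows[idx][ci] = float(raw)
            else:
                sheet.rows[idx][ci] = raw
    return sheet


def _sniff_type(values: list[str]) -> ColumnType:
    def all_parse(fn) -> bool:
        for v in values:
            try:
                fn(v)
            except ValueError:
                return False
        return bool(values)

    if all_parse(int):
        return ColumnType.INTEGER
    if all_parse(float):
        return ColumnType.REAL
    return ColumnType.STRING
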