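"""MDL Molfile V2000 / SDfile interop with an explicit loss ledger.

The V2000 connection table is the lowest common denominator of chemical
software; conversion into it is deliberately a *downstream*, potentially
irreversible step.  Every discarded feature is recorded in a
:class:`LossReport` so irreversibility is machine-readable, never silent.

Import freezes hydrogen counts: whatever the chosen hydrogen model infers
at parse time is written into explicit per-atom overrides, so the formula
can never drift when the record is re-interpreted later.  Export pins the
hydrogen count through the atom valence field whenever the effective
count disagrees with the legacy group-valence model a typical reader
would apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .elements import CARBON_GROUP, LEGACY_VALENCES, is_element
from .findings import Finding, Severity
from .formula import STRICT, HydrogenMode, implicit_hydrogen_count
from .model import Atom, Bond, Molecule, Stereo


class MolfileError(ValueError):
    pass


@dataclass
class LossEntry:
    locator: str
    code: str
    note: str

    def __str__(self) -> str:
        return f"{self.locator}: {self.code}: {self.note}"


@dataclass
class LossReport:
    """Machine-readable record of features a conversion discarded.

    Empty exactly when the conversion is invertible for that molecule
    (formula and bond graph survive a round trip).
    """

    entries: list[LossEntry] = field(default_factory=list)

    def add(self, locator: str, code: str, note: str) -> None:
        self.entries.append(LossEntry(locator, code, note))

    def __bool__(self) -> bool:
        return bool(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


_WEDGE_OUT = {Stereo.FLAT: 0, Stereo.INCLINED: 1,
              Stereo.DECLINED: 6, Stereo.UNKNOWN: 4}
_WEDGE_IN = {0: Stereo.FLAT, 1: Stereo.INCLINED,
             6: Stereo.DECLINED, 4: Stereo.UNKNOWN}
_LEGACY_CHARGE = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}

def _classify_extension(token: str) -> str:
    """'known' if the token parses under a reserved prefix, else 'unknown'."""
    if not token:
        return "unknown"
    p, payload = token[0], token[1:]
    if p in ("q", "a") and payload:
        return "known"
    if p in ("i", "m"):
        try:
            int(payload)
            return "known"
        except ValueError:
            return "unknown"
    if p == "z":
        try:
            float(payload)
            return "known"
        except ValueError:
            return "unknown"
    return "unknown"


# ---------------------------------------------------------------------------
# parsing


def parse_molfile(text: str,
                  hydrogen_mode: HydrogenMode = STRICT,
                  ) -> tuple[Molecule, list[Finding]]:
    """Parse a V2000 connection table.

    Atom labels outside the periodic table are kept as tokens and
    flagged.  Every atom leaves with an explicit virtual-hydrogen
    override computed under *hydrogen_mode* (unless the file pinned the
    valence itself), so the imported formula is frozen.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("truncated molfile: fewer than 4 lines")
    counts = lines[3]
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolfileError(f"malformed counts line: {counts!r}") from None
    if len(lines) < 4 + natoms + nbonds:
        raise MolfileError("truncated molfile: atom/bond block incomplete")

    findings: list[Finding] = []
    mol = Molecule()
    valences: dict[int, int] = {}
    for k in range(natoms):
        ln = lines[4 + k]
        try:
            x = float(ln[0:10])
            y = float(ln[10:20])
            z = float(ln[20:30])
            sym = ln[31:34].strip()
        except (ValueError, IndexError):
            raise MolfileError(f"malformed atom line {5 + k}: {ln!r}") from None
        atom = Atom(sym or "?", x, y)
        if z:
            atom.extensions.append(f"z{z:.4f}")
        code = _safe_int(ln[36:39])
        if code in _LEGACY_CHARGE:
            atom.charge = _LEGACY_CHARGE[code]
        elif code == 4:
            atom.unpaired = 1
        val = _safe_int(ln[48:51])
        if val:
            valences[len(mol.atoms) + 1] = val
        mapnum = _safe_int(ln[60:63])
        if mapnum:
            atom.extensions.append(f"m{mapnum}")
        idx = mol.add_atom(atom)
        if not is_element(sym):
            findings.append(Finding(
                Severity.WARNING, "non_element_label", f"atom {idx}",
                f"non-element label: {sym}"))

    for k in range(nbonds):
        ln = lines[4 + natoms + k]
        try:
            fr = int(ln[0:3])
            to = int(ln[3:6])
            order = int(ln[6:9])
        except (ValueError, IndexError):
            raise MolfileError(
                f"malformed bond line {5 + natoms + k}: {ln!r}") from None
        stereo = _WEDGE_IN.get(_safe_int(ln[9:12]), Stereo.FLAT)
        bond = Bond(fr, to, order if order in (1, 2, 3) else 1, stereo)
        if order not in (1, 2, 3):
            bond.extensions.append(f"qmdl-bond-type:{order}")
            findings.append(Finding(
                Severity.WARNING, "query_bond", f"bond {k + 1}",
                f"MDL bond type {order} imported as a query single bond"))
        mol.add_bond(bond)

    chg: dict[int, int] = {}
    iso: dict[int, int] = {}
    rad: dict[int, int] = {}
    saw_chg_or_rad = False
    for ln in lines[4 + natoms + nbonds:]:
        if ln.startswith("M  END"):
            break
        for tag, store in (("M  CHG", chg), ("M  ISO", iso), ("M  RAD", rad)):
            if ln.startswith(tag):
                parts = ln.split()
                vals = parts[3:]
                for a, v in zip(vals[0::2], vals[1::2]):
                    store[int(a)] = int(v)
                if tag != "M  ISO":
                    saw_chg_or_rad = True
    if saw_chg_or_rad:
        for a in mol.atoms:
            a.charge = 0
            a.unpaired = 0
        for i, v in chg.items():
            mol.atom(i).charge = v
        for i, v in rad.items():
            mol.atom(i).unpaired = {1: 0, 2: 1, 3: 2}.get(v, 0)
    for i, v in iso.items():
        mol.atom(i).set_isotope(v)

    # freeze hydrogens as explicit overrides
    for i in range(1, mol.num_atoms + 1):
        atom = mol.atom(i)
        occupied = mol.bond_order_sum(i) + atom.unpaired
        if i in valences:
            v = 0 if valences[i] == 15 else valences[i]
            atom.virtual_hydrogens = max(0, v - occupied)
        else:
            atom.virtual_hydrogens = implicit_hydrogen_count(
                mol, i, hydrogen_mode)
    return mol, findings


def _safe_int(s: str) -> int:
    try:
        return int(s)
    except (ValueError, TypeError):
        return 0


# ---------------------------------------------------------------------------
# writing


def write_molfile(mol: Molecule) -> tuple[str, LossReport]:
    """Emit a V2000 connection table plus the loss ledger.

    Abbreviations are expanded fully first (a recorded loss: the
    collapsed form cannot be reconstructed).  Zero-order bonds are
    written as single bonds, orders 4 and 5 downgraded likewise, query
    and unknown extensions dropped — each with a loss entry.  Refuses
    element tokens that are neither periodic-table symbols nor defined
    abbreviations.
    """
    loss = LossReport()
    work = mol
    if any(a.has_abbreviation for a in mol.atoms):
        from .abbrev import expand_fully

        for i, a in enumerate(mol.atoms, 1):
            if a.has_abbreviation:
                loss.add(f"atom {i}", "abbreviation-expanded",
                         f"inline abbreviation '{a.element}' expanded; "
                         f"the collapsed form is not representable")
        work = expand_fully(mol)

    for i, a in enumerate(work.atoms, 1):
        if not is_element(a.element):
            raise MolfileError(
                f"atom {i}: token {a.element!r} is not an element and has "
                f"no abbreviation definition; refusing to write")
        for t in a.extensions:
            if t.startswith("q") and len(t) > 1:
                loss.add(f"atom {i}", "query-extension",
                         f"atom query {t[1:]!r} not representable")
            elif _classify_extension(t) == "unknown":
                loss.add(f"atom {i}", "unknown-extension",
                         f"extension token {t!r} dropped")
        if a.unpaired > 2:
            loss.add(f"atom {i}", "unpaired-unrepresentable",
                     f"{a.unpaired} unpaired electrons exceed the M RAD range")

    lines = ["", "  minmol          2D", "",
             f"{work.num_atoms:3d}{work.num_bonds:3d}  0  0  0  0"
             f"  0  0  0  0999 V2000"]

    written_orders: dict[int, int] = {}
    for j, b in enumerate(work.bonds, 1):
        if b.order == 0:
            loss.add(f"bond {j}", "zero-order-bond",
                     "zero-order bond written as a single bond")
            written_orders[j] = 1
        elif b.order in (4, 5):
            loss.add(f"bond {j}", "high-order-bond",
                     f"order-{b.order} bond written as a single bond")
            written_orders[j] = 1
        else:
            written_orders[j] = b.order
        for t in b.extensions:
            if t.startswith("q") and len(t) > 1:
                loss.add(f"bond {j}", "query-extension",
                         f"bond query {t[1:]!r} not representable")
            elif _classify_extension(t) == "unknown":
                loss.add(f"bond {j}", "unknown-extension",
                         f"extension token {t!r} dropped")

    # occupied valence as the *written* connection table will carry it
    occ_out = {i: a.unpaired for i, a in enumerate(work.atoms, 1)}
    for j, b in enumerate(work.bonds, 1):
        occ_out[b.from_atom] += written_orders[j]
        occ_out[b.to_atom] += written_orders[j]

    chg_entries: list[tuple[int, int]] = []
    iso_entries: list[tuple[int, int]] = []
    rad_entries: list[tuple[int, int]] = []
    for i, a in enumerate(work.atoms, 1):
        z = a.z or 0.0
        eff = (a.virtual_hydrogens if a.virtual_hydrogens is not None
               else implicit_hydrogen_count(work, i, STRICT))
        # what a legacy reader would infer from the *written* table
        base = LEGACY_VALENCES.get(a.element, 0)
        if base == 0:
            legacy_auto = 0
        elif a.element in CARBON_GROUP:
            legacy_auto = max(0, base - abs(a.charge) - occ_out[i])
        else:
            legacy_auto = max(0, base + a.charge - occ_out[i])
        val = 0
        if eff != legacy_auto:
            total = occ_out[i] + eff
            val = 15 if total == 0 else total
        lines.append(
            f"{a.x:10.4f}{a.y:10.4f}{z:10.4f} {a.element:<3} 0  0  0  0  0"
            f"{val:3d}  0  0  0{a.mapping:3d}  0  0")
        if a.charge:
            chg_entries.append((i, a.charge))
        if a.isotope:
            iso_entries.append((i, a.isotope))
        if a.unpaired in (1, 2):
            rad_entries.append((i, a.unpaired + 1))

    for j, b in enumerate(work.bonds, 1):
        lines.append(f"{b.from_atom:3d}{b.to_atom:3d}{written_orders[j]:3d}"
                     f"{_WEDGE_OUT[b.stereo]:3d}  0  0  0")

    for tag, entries in (("CHG", chg_entries), ("ISO", iso_entries),
                         ("RAD", rad_entries)):
        for start in range(0, len(entries), 8):
            chunk = entries[start:start + 8]
            parts = "".join(f"{a:4d}{v:4d}" for a, v in chunk)
            lines.append(f"M  {tag}{len(chunk):3d}{parts}")
    lines.append("M  END")
    return "\n".join(lines) + "\n", loss


# ---------------------------------------------------------------------------
# SDfiles


def parse_sdfile(text: str, hydrogen_mode: HydrogenMode = STRICT,
                 ) -> list[tuple[Molecule, dict[str, str], list[Finding]]]:
    """Split an SDfile into (molecule, data fields, findings) records."""
    records: list[tuple[Molecule, dict[str, str], list[Finding]]] = []
    for k, chunk in enumerate(text.split("$$$$")):
        if not chunk.strip():
            continue
        if k and chunk.startswith("\n"):
            # drop only the newline that terminated the previous $$$$;
            # the next (possibly empty) line is the record's title
            chunk = chunk[1:]
        if "M  END" not in chunk:
            raise MolfileError("SD record without M  END")
        mol_text, _, rest = chunk.partition("M  END")
        mol, findings = parse_molfile(mol_text + "M  END\n", hydrogen_mode)
        fields: dict[str, str] = {}
        cur: str | None = None
        buf: list[str] = []
        for ln in rest.splitlines():
            if ln.startswith(">"):
                if cur is not None:
                    fields[cur] = "\n".join(buf).rstrip("\n")
                lo, hi = ln.find("<"), ln.rfind(">")
                cur = ln[lo + 1:hi] if 0 <= lo < hi else ln[1:].strip()
                buf = []
            elif cur is not None:
                if ln == "" and buf:
                    fields[cur] = "\n".join(buf)
                    cur = None
                    buf = []
                elif ln != "" or buf:
                    buf.append(ln)
        if cur is not None:
            fields[cur] = "\n".join(buf).rstrip("\n")
        records.append((mol, fields, findings))
    return records


def write_sd_record(mol: Molecule, fields: dict[str, str],
                    ) -> tuple[str, LossReport]:
    """One SDfile record: molfile, data fields, ``$$$$`` terminator."""
    text, loss = write_molfile(mol)
    out = [text.rstrip("\n")]
    for name, value in fields.items():
        out.append(f"> <{name}>")
        out.append(value)
        out.append("")
    out.append("$$$$")
    return "\n".join(out) + "\n", loss
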