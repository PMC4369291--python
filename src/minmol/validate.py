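"""The accept/reject gate: entries with zero or multiple plausible
interpretations are rejected before release.

"Zero interpretations" is operationalized as any uninterpretable token or
structure (ERROR class): a non-element label with no inline abbreviation
definition, or a template submitted without an enumeration recipe.
"Multiple interpretations" covers constructs whose plausible readings
diverge — most prominently a bare metal outside the automatic-hydrogen
element set whose drawn valence is open (different readers will hydrogenate
it differently) — and these are WARNINGS prompting an explicit fix
(unpaired electrons, a charge, or a pinned hydrogen count), never silent
rewrites: the originating scientist is always the final arbiter, and this
gate never mutates its input.

Advisory checks follow curation practice: covalently bound salts (Na–Cl),
pentavalent neutral nitro groups, hypervalent light atoms (a warning, not
an error — carboranes are legal).  The rule registry is small and
extensible.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass, field

import networkx as nx

from .abbrev import splice_fragment
from .datasheet import ColumnType, DataSheet
from .elements import (
    ALKALI_METALS,
    AUTO_HYDROGEN_ELEMENTS,
    HALOGENS,
    LEGACY_VALENCES,
    STRICT_VALENCES,
    is_element,
)
from .findings import Finding, Severity
from .formula import STRICT, FormulaMap, HydrogenMode, molecular_formula
from .model import Molecule, check_graph, net_formal_charge

_PLACEHOLDER_RE = re.compile(r"^(X|R\d*)$")


def is_placeholder(token: str) -> bool:
    """Exactly ``X``, ``R`` or ``R<digits>``, case-sensitive."""
    return bool(_PLACEHOLDER_RE.match(token))


class EntryKind(enum.Enum):
    MOLECULE = "MOLECULE"
    TEMPLATE = "TEMPLATE"
    QUERY = "QUERY"


def classify_entry(mol: Molecule) -> EntryKind:
    """TEMPLATE if any undefined placeholder token, QUERY if any query
    extension, otherwise MOLECULE."""
    for a in mol.atoms:
        if is_placeholder(a.element) and not a.has_abbreviation:
            return EntryKind.TEMPLATE
    for a in mol.atoms:
        if a.query_tokens:
            return EntryKind.QUERY
    for b in mol.bonds:
        if b.query_tokens:
            return EntryKind.QUERY
    return EntryKind.MOLECULE


def validate_molecule(mol: Molecule,
                      mode: HydrogenMode = STRICT) -> list[Finding]:
    """Run the rule registry; pure, deterministic, stable finding order."""
    findings: list[Finding] = []
    for v in check_graph(mol):
        findings.append(Finding(Severity.ERROR, "invalid_graph",
                                v.locator, f"{v.rule}: {v.message}"))
    if findings:
        return findings  # structural breakage shadows chemistry rules

    if classify_entry(mol) is EntryKind.TEMPLATE:
        labels = sorted({a.element for a in mol.atoms
                         if is_placeholder(a.element)
                         and not a.has_abbreviation})
        findings.append(Finding(
            Severity.ERROR, "template_without_recipe", "molecule",
            f"placeholders {', '.join(labels)} make this a template; it "
            f"needs an enumeration recipe before submission"))

    for i, a in enumerate(mol.atoms, 1):
        loc = f"atom {i}"
        el = a.element
        if (not is_element(el) and not a.has_abbreviation
                and not is_placeholder(el)):
            findings.append(Finding(
                Severity.ERROR, "uninterpretable_label", loc,
                f"label {el!r} is not an element, and so is meaningless"))
            continue
        occupied = mol.bond_order_sum(i) + a.unpaired
        # hypervalence looks at drawn bonds only: unpaired electrons
        # legitimately occupy valence without being bonds
        if el in AUTO_HYDROGEN_ELEMENTS:
            limit = STRICT_VALENCES[el][-1] + abs(a.charge)
            if mol.bond_order_sum(i) > limit:
                findings.append(Finding(
                    Severity.WARNING, "hypervalent_atom", loc,
                    f"{el} occupies valence {occupied}, above {limit}; "
                    f"usually a mistake (though e.g. carboranes are legal)"))
        if (el == "N" and a.charge == 0 and a.virtual_hydrogens is None
                and occupied >= 5):
            n_double_o = sum(
                1 for b in mol.bonds_of(i)
                if b.order == 2 and mol.atom(b.other(i)).element == "O"
                and mol.atom(b.other(i)).charge == 0)
            if n_double_o >= 2:
                findings.append(Finding(
                    Severity.WARNING, "pentavalent_nitro", loc,
                    "neutral pentavalent nitro pattern; charge-separated "
                    "form intended?"))
        if (is_element(el) and el not in AUTO_HYDROGEN_ELEMENTS
                and el != "H"
                and a.virtual_hydrogens is None and a.unpaired == 0
                and a.charge == 0 and LEGACY_VALENCES.get(el, 0) > 0):
            if 0 < occupied < LEGACY_VALENCES[el]:
                findings.append(Finding(
                    Severity.WARNING, "ambiguous_valence", loc,
                    f"{el} with open valence and no explicit hydrogen "
                    f"count, unpaired electrons or charge: different "
                    f"readers will interpret the hydrogenation "
                    f"differently"))

    for j, b in enumerate(mol.bonds, 1):
        if b.order >= 1:
            e1 = mol.atom(b.from_atom).element
            e2 = mol.atom(b.to_atom).element
            if ({e1, e2} & ALKALI_METALS) and ({e1, e2} & HALOGENS):
                findings.append(Finding(
                    Severity.WARNING, "covalent_salt", f"bond {j}",
                    f"covalent bond between {e1} and {e2}; an ionic pair "
                    f"was probably intended"))

    if (len(mol.connected_components()) == 1 and mol.num_atoms
            and net_formal_charge(mol) != 0):
        findings.append(Finding(
            Severity.INFO, "net_charge", "molecule",
            f"single-component entry has net charge "
            f"{net_formal_charge(mol):+d}"))
    return findings


class GateDecision(enum.Enum):
    ACCEPT = "ACCEPT"
    REJECT = "REJECT"


@dataclass
class GateResult:
    decision: GateDecision
    findings: list[Finding] = field(default_factory=list)
    #: computed formulas for accepted molecules, keyed by locator — the
    #: feedback shown to the submitter alongside any residual warnings
    formulas: dict[str, FormulaMap] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.decision is GateDecision.ACCEPT


def gate_entry(payload: Molecule | DataSheet,
               mode: HydrogenMode = STRICT) -> GateResult:
    """REJECT iff any ERROR finding across all molecules/cells."""
    findings: list[Finding] = []
    molecules: list[tuple[str, Molecule]] = []
    if isinstance(payload, Molecule):
        molecules.append(("molecule", payload))
        findings.extend(validate_molecule(payload, mode))
    else:
        for r, row in enumerate(payload.rows):
            for c, value in zip(payload.columns, row):
                if c.type is ColumnType.MOLECULE and value is not None:
                    loc = f"row {r}, column {c.name!r}"
                    molecules.append((loc, value))
                    for f in validate_molecule(value, mode):
                        findings.append(Finding(
                            f.severity, f.code,
                            f"{loc}: {f.locator}", f.message))
    if any(f.severity is Severity.ERROR for f in findings):
        return GateResult(GateDecision.REJECT, findings)
    formulas = {loc: molecular_formula(m, mode=mode)
                for loc, m in molecules}
    return GateResult(GateDecision.ACCEPT, findings, formulas)


# ---------------------------------------------------------------------------
# template enumeration


def _iso_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for i, a in enumerate(mol.atoms, 1):
        g.add_node(i, element=a.element, charge=a.charge,
                   unpaired=a.unpaired, isotope=a.isotope,
                   vh=a.virtual_hydrogens)
    for b in mol.bonds:
        g.add_edge(b.from_atom, b.to_atom, order=b.order)
    return g


def _same_species(m1: Molecule, m2: Molecule) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge", "unpaired", "isotope", "vh"],
        [None] * 5)
    em = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    return nx.is_isomorphic(_iso_graph(m1), _iso_graph(m2),
                            node_match=nm, edge_match=em)


def enumerate_template(template: Molecule,
                       substitutions: dict[str, list[Molecule]],
                       ) -> list[Molecule]:
    """Enumerate the chemical species a template encodes.

    *substitutions* maps each placeholder label to its candidate
    fragments (each carrying one attachment marker); every atom sharing a
    label receives the same fragment within one combination.  The
    Cartesian product is grafted and graph-identical duplicates removed.
    """
    if classify_entry(template) is not EntryKind.TEMPLATE:
        raise ValueError("entry is not a template")
    labels = sorted({a.element for a in template.atoms
                     if is_placeholder(a.element) and not a.has_abbreviation})
    for label in labels:
        if not substitutions.get(label):
            raise ValueError(f"placeholder {label!r} has no substitution list")

    results: list[Molecule] = []
    for combo in itertools.product(*(substitutions[lb] for lb in labels)):
        chosen = dict(zip(labels, combo))
        work = template.copy()
        while True:
            idx = next((i for i, a in enumerate(work.atoms, 1)
                        if a.element in chosen and not a.has_abbreviation),
                       None)
            if idx is None:
                break
            work = splice_fragment(work, idx, chosen[work.atom(idx).element])
        if classify_entry(work) is not EntryKind.MOLECULE:
            raise ValueError("substitution left a non-molecule entry")
        if not any(_same_species(work, prev) for prev in results):
            results.append(work)
    return results
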