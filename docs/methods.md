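# Methods

## The problem

Most 2D chemical structure formats cannot guarantee that an algorithm
recovers the correct molecular formula from a drawing. The failures
concentrate in two places: implicit hydrogens (valence rules are poorly
defined for unusual bonding, and there is often no way to override the
default) and abbreviations (a node labelled "Ph" means nothing unless the
reading software happens to carry the same lookup table). `minmol`
implements a deliberately minimal data model in which both problems have
exact answers, plus the surrounding machinery a machine-first data
pipeline needs: a gate that rejects ambiguous entries, an honest
(loss-ledgered) downconversion to MDL Molfile, a typed tabular container,
and vector depiction.

## Data model

A molecule is an ordered atom list and an ordered bond list, nothing
else. Per atom: element token (any non-empty string), x/y in
quasi-Ångström units (idealized bond length 1.5, y up), integer formal
charge, unpaired-electron count, a virtual-hydrogen setting (automatic,
or an explicit non-negative pin), and an ordered list of opaque extension
tokens. Per bond: two 1-based atom indices, integer order 0–5, a stereo
drawing style (flat/inclined/declined/unknown, stored but never
chemically interpreted), and extensions.

Reserved extension prefixes (z coordinate, isotope mass, mapping number,
query, abbreviation) are single letters followed directly by the payload.
A token that does not parse under its prefix is treated as unknown and
carried verbatim; that is the compatibility contract, not an error.

Element tokens are not validated by the model. A non-element token makes
the record a template or query — a classification performed by the
validation layer, never a parse failure.

## Hydrogen inference

Two models, selected per call:

**Strict (the default and the format's semantics).** Hydrogens are
computed only for C, N, O, P, S and are zero for everything else. Let
`occupied = Σ bond orders + unpaired` (zero-order bonds contribute
nothing). Base valences: C 4, N 3, O 2; the multivalent P ∈ {3,5} and
S ∈ {2,4,6} take the smallest allowed valence ≥ occupied. Charge adjusts
the target: carbon loses |charge| (both carbanion and carbenium have
three hydrogens from a bare atom), heteroatoms add the signed charge
(hydroxide 1 H, ammonium 4 H). Hydrogens = max(0, adjusted − occupied).
An explicit per-atom pin always wins, in either model.

**Legacy.** Emulates the group-valence guessing common in Molfile
readers: B 3; C, Si, Ge, Sn, Pb 4; N, P, As, Sb 3; O, S, Se, Te 2;
halogens 1; all others 0, same occupancy arithmetic. The charge rule is
extrapolated (a repo choice, since the strict rule only names C and
N/O/P/S): the carbon group subtracts |charge|, every other tabled
element adds the signed charge, clamped at zero. This model exists to
reproduce — on import, and only on request — the reading under which a
bare two-coordinate tin dichloride becomes H2SnCl2. It is never the
default interpretation.

Zero-order bonds are the piece that keeps dative and multicentre
attachments (η-bonded ligands, adducts) formula-safe: they connect atoms
without consuming valence on either end. A "lone pair" disambiguation is
expressed through the unpaired-electron field, which occupies valence
without adding bonds; a carbene-like carbonyl carbon is `:C=O` with
unpaired = 2 and therefore zero inferred hydrogens.

The hypervalence *warning* compares drawn bond order sums only (not
unpaired electrons) against the largest strict valence: flagging the
recommended lone-pair representation would defeat its purpose.

## Formulas

`molecular_formula` counts explicit atoms under `(element, isotope)` keys
(mass 0 = natural abundance), adds inferred hydrogens, and appends every
uninterpretable label to an ordered `unknown_labels` list rather than
guessing. Rendering is Hill order — C, H, then alphabetical; plain
alphabetical when no carbon — with isotopes bracketed (`[2H]4`; deuterium
is not rendered as "D", a documented choice) and unknown labels bracketed
at the end, e.g. `C14H28Fe2[CO][OC]`. Displaying that string to the
submitting chemist is the cheapest possible education about what the
drawing actually says.

## Abbreviations

An abbreviation atom carries its defining fragment inline (there is no
global dictionary on purpose: none exists in the world, so every file
must be self-contained). The fragment contains exactly one attachment
pseudo-atom `*` bonded to the attachment atom; the marker consumes bond
order (so an ethyl fragment's implied formula is C2H5, not C2H6) but
contributes no atom. Splicing deletes the marker, reattaches the host
bond at the attachment atom keeping the host bond's order/stereo/
extensions, and rigid-transforms the fragment so the new bond has length
1.5 pointing away from the host. Definitions nest arbitrarily; expansion
is a fixpoint with cycle detection by label chain (the depth bound is the
number of distinct labels, so termination is structural).

`subsume_fragment` inverts expansion: a connected selection with at most
one crossing bond collapses to a fresh abbreviation node. A selection
with zero crossing bonds (the whole component — how the single-node
"abbreviation of abbreviations" is built) joins its marker by a
zero-order bond so no valence is consumed anywhere. Subsume-then-expand
preserves element counts exactly; unknown-label *order* may permute with
atom order, which the tests treat as equivalent.

## Serialization

The wire grammar is line-oriented UTF-8, TAB-separated fields with
backslash escaping, a counts header and a terminator; coordinates print
with fixed 4-decimal precision, and automatic hydrogens serialize as `.`
(distinct from an explicit 0). Abbreviation payloads are complete nested
documents carried inside one escaped token, so recursion costs nothing.
The dialect is frozen by golden files in `tests/golden/`; unknown tokens
round-trip byte-for-byte, and `write ∘ parse ∘ write = write` holds
byte-for-byte.

## Molfile interop

Export targets the lowest-common-denominator V2000 subset: charges via
`M  CHG`, isotopes via `M  ISO`, radicals via `M  RAD`, wedges via the
bond stereo column. Zero-order bonds downgrade to single bonds (not
query type 8, which most readers refuse) and orders 4–5 likewise — every
such downgrade, along with expanded abbreviations, dropped query/unknown
extensions and unrepresentable radical counts, lands in a machine-
readable `LossReport`. The report is empty exactly when the written file
reparses to the same formula and bond graph.

Two pinning rules keep formulas honest across the boundary. On export,
whenever the effective hydrogen count disagrees with what a legacy
group-valence reader would infer *from the file as written*, the atom
valence field pins it (15 encodes zero). On import, every atom's
hydrogen count is frozen into an explicit override — computed from the
valence field when present, else under the caller-chosen hydrogen model —
so a record interpreted once can never silently drift when re-read.

## Datasheets and aspects

A datasheet is a strongly typed table (molecule, string, integer, real,
boolean) serialized as XML, with molecule cells embedding the molecule
serialization as escaped text and null cells as absent elements (so
numeric columns stay type-clean). The header carries ordered named
extensions; recognized names — Solvent, SARTable, Reaction, Experiment —
parse into typed aspect views, unrecognized ones survive verbatim.

Aspect payloads are JSON (a repo-defined minimal schema, frozen by the
fixture round-trips): Solvent lists display roles and default units per
column and is purely suggestive; SARTable names scaffold, substituent,
composite-molecule and property columns (with units and operating
range); Reaction groups columns into one step's reactant/reagent/product
roles; Experiment extends Reaction with multiple steps and per-component
quantity columns. Tolerance is the contract: generic edits through
aspect-unaware software never invalidate a payload, and `repair_aspect`
recreates any deleted required column null-filled with its declared type,
idempotently. SAR recomposition grafts substituents onto R-labelled
placeholders by exact label match using the same splice as abbreviations.

SD export writes one record per row with other columns as data fields;
typing and aspects are logged as lost, and re-import demonstrates it
(booleans come back as strings — sniffing is integer → real → string
only, because SD data genuinely cannot distinguish a boolean from text).

## The gate

"Zero or more than one interpretation" is operationalized as: ERROR for
anything uninterpretable (a non-element, non-placeholder label with no
inline definition; a template submitted without an enumeration recipe;
a broken graph), and WARNING for divergent plausible readings — most
importantly a non-C/N/O/P/S element with open legacy valence and no
explicit disambiguation (the divalent-tin case; any of unpaired
electrons, a charge, or a pinned hydrogen count silences it). Advisory
rules follow curation practice: covalent alkali–halide bonds, neutral
pentavalent nitro, hypervalent light atoms — warnings, never errors,
because carboranes are real and the originating scientist is the final
arbiter. The gate rejects on any ERROR and otherwise returns the
computed formulas for display; it never mutates input, since proactive
"fixing" of structures does more harm than good.

Template enumeration takes per-label fragment lists, grafts the
Cartesian product (atoms sharing a label receive the same fragment
within a combination), and removes graph-identical duplicates via
VF2 isomorphism with categorical node/edge attributes (networkx); the
graphs involved are tiny, so worst-case matching cost is irrelevant.

## Depiction

Stored coordinates are authoritative. `layout_fragment` exists only for
generated fragments: single rings go on regular polygons with side 1.5,
chains zigzag at 120° with collision-avoiding fallback angles, and fused
polycycles are declared unsupported so callers keep original
coordinates (full de-novo layout is deliberately out of scope). The
renderer emits an intermediate primitive list — lines, dashed lines for
zero-order bonds, filled polygons for inclined wedges (narrow end at the
bond's from-atom), hash sets for declined, a wavy path for unknown
stereo, text for labels/charges/isotopes — written either as
deterministic SVG (stable element order, 2-decimal coordinates) or
rasterized to PNG via Pillow as a convenience. Carbon labels are
suppressed unless charged, isotopic, abbreviated or isolated. Reaction
schemes place reactants left of a generated arrow, products right,
reagents above, steps stacked, all in one coordinate system.

## Fixtures and randomized inputs

Every worked structure is built programmatically: the bromobenzene pair,
triethylsilane at three abbreviation depths (silicon carries an explicit
hydrogen pin of 1, since it is outside the automatic set), the
divalent-tin triple (naive / lone-pair / pinned-zero), the bare C5 ring,
deuterated ammonium bromide, the X/R template with two substituent
choices per site, the iron-dimer pair (machine-friendly with zero-order
bonds and carbene carbonyls; human-friendly with CO/OC text labels,
reconstructed so its literal reading is C14H28Fe2[CO][OC]), plus the
rule-triggering misdrawings and four aspect-bearing datasheets. Golden
`.el` files freeze the dialect.

The random generator produces connected C/N/O/P/S molecules (orders 1–3,
charges −1..+1, optional ring closure) and a decorated variant with
unknown extension tokens, isotopes and hydrogen pins. It emulates
topology and annotation diversity, not chemical plausibility — passing
tests show the arithmetic and the round-trip contracts are right, not
that real-world drawings are well handled; the fixtures carry that
burden.

The strict-hydrogen test oracle re-derives counts by downward search
over the valence equation, independently of the library arithmetic, and
RDKit serves as an external cross-check that exported V2000 files mean
what we think they mean.

## Numerical and policy choices

- Tolerances: layout distances asserted to 1e−6; everything else is
  integer or exact text.
- Serialization precision: 4 decimals for coordinates, 2 for SVG.
- Bond orders 4 and 5 are stored and summed but carry no special
  chemistry; sizes used in tests and the acceptance script are the
  natural sizes of the worked structures (2–20 atoms) plus 100–1000
  randomized molecules of 2–9 atoms.
- Ties in enumeration order follow label sort and input list order;
  dedup keeps the first representative.

## Known limitations

No aromatic bond type (integer orders only), no stereo perception, no
3D operations, no S-groups/Rgroup/V3000, no tautomer or standardization
rewriting, no name↔structure reconciliation, no exact-mass computation.
The legacy charge rule outside the named groups is an extrapolation.
Layout handles one ring; depiction aims for clarity, not publication
aesthetics.
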