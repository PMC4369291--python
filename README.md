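# minmol

A minimalist, machine-first toolkit for 2D chemical structures and
tabular chemical data — for the people who build data-entry, curation
and sharing pipelines where records must be correct *to an algorithm*
first, and pretty second.

Two litmus questions drive the design:

1. Can an algorithm determine the molecular formula of this drawing
   correctly and unambiguously?
2. Can software that does not understand a feature still read, view,
   modify and write the record without destroying it?

## What is in the box

- **Core model** — atoms (element token, 2D coordinates, charge,
  unpaired electrons, virtual-hydrogen setting, opaque extensions) and
  bonds (order 0–5, drawing stereo, extensions). Zero-order bonds
  connect atoms without consuming valence, which keeps formulas of
  dative/multicentre structures exact.
- **Formula engine** — strict hydrogen inference (automatic only for
  C, N, O, P, S; H = max(0, adjusted valence − Σ bond orders − unpaired);
  explicit per-atom pins always win) plus a legacy group-valence mode
  that reproduces, on request, how common Molfile readers misread e.g.
  a bare SnCl2 drawing as H2SnCl2.
- **Inline abbreviations** — a "Ph" node carries the phenyl fragment
  and its attachment point inside the same file; definitions nest
  recursively, expand confluently, and fragments can be subsumed back
  into abbreviations.
- **Serialization** (`.el`, MIME `chemical/x-sketchel`) — line-oriented,
  forward- and backward-compatible: unknown extension tokens survive
  read/modify/write byte-for-byte.
- **MDL Molfile V2000 / SDfile interop** — lowest-common-denominator
  export with a machine-readable `LossReport` of every discarded
  feature; import freezes hydrogens as explicit pins so formulas never
  drift.
- **Datasheets** (`.ds`) — strongly typed columns (molecule, string,
  integer, real, boolean) in XML, with tolerant header *aspects*
  (Solvent, SARTable, Reaction, Experiment) that survive editing by
  aspect-unaware software and repair themselves when required columns
  are deleted.
- **Validation gate** — entries with zero interpretations (meaningless
  labels, recipe-less templates) are rejected; divergent-reading
  constructs warn; warnings never block, because the originating
  scientist is the final arbiter. Markush-style templates enumerate to
  concrete species.
- **Depiction** — deterministic SVG (dashed zero-order bonds, wedges,
  isotope/charge scripts), optional PNG raster, reaction-scheme layout.

## Worked example

```python
import minmol as m

# bromobenzene with the ring subsumed into a "Ph" abbreviation
mol = m.build_fixture("bromobenzene_full")
print(m.heavy_atom_count(mol))                       # 7
ph = m.subsume_fragment(mol, [1, 2, 3, 4, 5, 6], "Ph")
print(m.heavy_atom_count(ph))                        # 2
print(m.formula_to_string(m.molecular_formula(ph)))  # C6H5Br

# the tin(II) chloride ambiguity, and its explicit fix
sn = m.build_fixture("sncl2_naive")
print(m.implicit_hydrogen_count(sn, 1, m.STRICT))    # 0
print(m.implicit_hydrogen_count(sn, 1, m.LEGACY))    # 2   (H2SnCl2!)
for f in m.validate_molecule(sn):
    print(f)  # WARNING [ambiguous_valence] atom 1: Sn with open valence ...

# the gate: same chemistry, two drawings
naive = m.gate_entry(m.build_fixture("fe_dimer_naive"))
print(naive.decision.value)                          # REJECT
machine = m.gate_entry(m.build_fixture("fe_dimer_machine"))
print(machine.decision.value)                        # ACCEPT
print(m.formula_to_string(list(machine.formulas.values())[0]))
                                                     # C14H10Fe2O4
```

The numbers mean: a fully drawn bromobenzene has 7 heavy atoms and the
abbreviated form 2 nodes, yet both carry the same exact formula; a bare
tin drawing is read two different ways by two legitimate hydrogen
models, which is precisely why the gate warns until the drawing pins one
of them; and the organometallic dimer drawn with text-label carbonyls is
meaningless to a machine (rejected), while the zero-order-bond drawing
of the same compound yields a clean formula (accepted).

The same operations are available from the shell:

```sh
minmol fixture triethylsilane_meta -o t.el
minmol formula t.el          # C6H16Si
minmol validate t.el         # ... ACCEPT
minmol render t.el t.svg --scheme dark
minmol sheet export sar.ds sar.sdf --column Molecule
```

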