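# sketchmol

A headless, scriptable 2D molecular structure sketching engine.

Interactive web structure editors let a chemist click together a small
molecule and hand the result to a database or registration system as an MDL
molfile. `sketchmol` provides the same editing semantics — sprouting atoms,
stamping ring templates, fusing and spiro-attaching rings, wedge/hash stereo
marks, automatic valence-dependent atom labels, query atoms for substructure
input — as a pure Python library plus a thin command-line tool, with no GUI:
edits are replayable text scripts, so structure construction becomes
reproducible and testable. It is aimed at people building chemistry-enabled
web back-ends, test fixtures for cheminformatics pipelines, or batch
depiction jobs.

## The model

A molecule is a single **connection table**: an ordered atom list (element
or query symbol, 2D coordinates, formal charge *q* ∈ [−15, +15]) and a bond
list (order 1–3, optional wedge/hash mark on single bonds). Disconnected
fragments (salts) live in the same table. Atom identifiers are stable and
never reused, so scripts replay deterministically.

**Implicit hydrogens and labels.** An atom's label is a pure function of its
symbol, charge and bond-order sum *b*. The implicit hydrogen count is the
free valence *v* − *b* for the lowest standard valence state *v* ≥ *b* of
the element (S: 2, 4, 6; P: 3, 5; I: 1, 3, 5; single-valued for C, N, O and
the light halogens). Charge is folded in asymmetrically, matching mainstream
toolkits: a cation uses the valence ladder of the isoelectronic element
*Z* − *q* (N⁺ binds like carbon, hence NH₄⁺), while an anion keeps its own
ladder with the free valence reduced by |*q*| (O⁻ → "O−", S⁻ with two bonds
climbs to the S(IV) state). Bonded, uncharged carbon is drawn as a bare
vertex; everything else renders as symbol + H count + charge ("NH2", "OH",
"O-", "NH4+"). Query symbols **A** (any atom except H), **Q** (any except H
and C) and **X** (any halogen) carry no hydrogens and render as themselves.

**Geometry.** The standard bond length is *L* = 1.5 coordinate units. New
substituents sprout on a 30° angular grid at the candidate angle with the
greatest clearance from existing bonds (capped at 120°, smallest angle wins
ties — which yields conventional zig-zag chains). The seven ring templates
(cyclopropane … cyclooctane, plus benzene with alternating bond orders) are
regular polygons. A template dropped on a bond is **fused** (shares the
bond) on the less crowded side, or mirrored across the bond line with the
shift flag; dropped on an atom it attaches through a single bond, or shares
the atom (**spiro**) with the shift flag. New ring vertices landing within
0.25 *L* of an existing atom merge onto it, which is how condensed
polycyclics stay clean.

**I/O.** Molfile V2000 in and out, byte-reproducible fixed-width output:
charges as `M  CHG` records, wedge/hash as bond-stereo codes 1/6, at most
999 atoms and bonds (the format's three-digit counts fields). The reader
accepts LF, CRLF and bare CR line endings and honours the CTfile rule that
any `M  CHG` record supersedes the legacy atom-block charge column. SVG
depiction renders labels, parallel-line multiple bonds, filled/hashed
wedges, with fit-to-canvas plus move (offset) and zoom.

## Worked example

```python
from sketchmol import Molecule, apply_script, atom_label, write_molfile

mol = apply_script(Molecule(), """
    template name=benzene
    add_atom symbol=O attach=0
    add_atom symbol=N attach=3
""")
print([atom_label(mol, a.id) for a in mol.atoms])
print(write_molfile(mol)[:200])
```

prints

```
['', '', '', '', '', '', 'OH', 'NH2']


  sketchmol       2D

  8  8  0  0  0  0  0  0  0  0999 V2000
    0.0000    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
...
```

The six ring carbons are bare vertices (empty labels); the sprouted oxygen
and nitrogen label themselves `OH` and `NH2` from their free valences. The
counts line says 8 atoms, 8 bonds; the benzene template contributed three
order-2 lines to the bond block. More narrative walk-throughs live in
`examples/` (ring fusion/spiro bookkeeping, stereo depiction, line-ending
tolerant molfile exchange).

## Edit scripts

One command per line, `verb key=value ...`, `#` comments. Verbs:

| verb | arguments |
|------|-----------|
| `add_atom` | `symbol=` [`attach=` atom] [`x=` `y=`] |
| `delete_atom` | `atom=` |
| `add_bond` | `a1=` `a2=` [`order=1`] |
| `delete_bond` | `bond=` or `a1= a2=` [`keep_orphans=false`] |
| `set_element` | `atom=` `symbol=` |
| `set_charge` | `atom=` `delta=±1` or `value=` |
| `set_bond_order` | `bond=` `order=1|2|3|cycle` |
| `set_stereo` | `bond=` `stereo=none|up|down` |
| `template` | `name=` [`atom=` or `bond=`] [`shift=false`] [`x=` `y=`] |
| `transform` | [`dx=` `dy=`] [`scale=1`] |

A script is atomic: the first failing command aborts it and the input
molecule is untouched. `shift=true` selects the modified behaviours: spiro
attachment on an atom target, mirrored fusion on a bond target;
`keep_orphans=true` preserves atoms orphaned by a bond deletion, creating
disconnected fragments.

## Command line

```sh
sketchmol edit  [-i in.mol] -s script.txt -o out.mol [--crlf] [-v]
sketchmol render -i in.mol -o out.svg [--width --height --margin --zoom --dx --dy]
```

`-` means stdin/stdout, so a web back-end can pipe molfiles through the
tool. Exit codes: 2 molfile parse error, 3 script error, 4 over the
999-atom/bond cap, 1 anything else. A batch "slide show" over a directory
of molfiles is a shell loop away:
`for f in *.mol; do sketchmol render -i "$f" -o "${f%.mol}.svg"; done`.

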