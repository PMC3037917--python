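# Methods

This note records the models and conventions behind `sketchmol`, the
choices made where sketching conventions are genuinely open, and what the
test suite does and does not establish.

## Connection-table model

One molecule is one connection table. Atoms carry an element symbol (any
periodic-table symbol) or one of the query wildcards A/Q/X, 2D coordinates
in unitless molfile coordinates, and an integer formal charge limited to
[−15, +15] — the representable range of a V2000 `M  CHG` value. Bonds have
order 1–3 and an optional wedge (up) or hash (down) mark, restricted to
single bonds; the "either" stereo code 4 is read as unmarked. Multiple
disconnected fragments are allowed inside the table. Atom and bond ids are
monotonically assigned and never reused, and every editing operation is
copy-on-write, which gives two properties the tests rely on: edit scripts
are atomic (a failed command cannot leave a half-applied state) and replay
is bit-deterministic, including molfile export order (insertion order).

## Valence and label model

The displayed label of an atom is a pure function of (symbol, charge,
bond-order sum). Implicit hydrogens are the free valence of the lowest
standard valence state that accommodates the existing bonds:

* valence ladders: H 1; B 3; C 4; N 3; O 2; F/Cl/Br 1; Si 4; P 3,5;
  S/Se/Te 2,4,6; I 1,3,5; plus the rest of main groups 1–2 and 13–18.
  Elements outside the table (metals, lanthanides) get no implicit
  hydrogens — they degrade to bare labelled symbols rather than erroring.
* charge folding is asymmetric, following the convention shared by
  mainstream editors and toolkits: a **cation** is treated as isoelectronic
  with element *Z* − *q* and uses that element's ladder (N⁺ → C's 4,
  Cl⁺ → S's 2,4,6); an **anion** keeps its own ladder with the free valence
  reduced by |*q*| (O⁻ binds once; S⁻ with two bonds is an S(IV)-like
  centre with one free valence), except for the early elements of groups
  1–2/13 where the extra electron adds capacity (B⁻ binds four).
* query atoms and explicit H nodes never acquire implicit hydrogens: a
  wildcard that matches "any atom except H" has no meaningful H count, and
  an explicit H is already a hydrogen.

This model was chosen over the simpler "single valence ± charge" arithmetic
because the simpler rule contradicts both chemical usage and independent
toolkits for hypervalent centres and halogen cations; the test suite checks
the full table {C,N,O,S,P,F,Cl,Br,I} × charges {−1,0,+1} × bond sums {0..4}
cell-by-cell against RDKit and requires exact agreement. One consequence is
deliberate: the implicit-H count is **not** globally monotone in the bond
count for multi-valence elements (S goes 0 → 1 implicit H when its third
bond forces the S(IV) state). The monotonicity property test therefore
covers single-valence elements only.

Labels: bonded, uncharged carbon is an empty label (a vertex); otherwise
symbol + `H`/`Hn` when the count is ≥ 1 + charge suffix in magnitude-first
form (`+`, `-`, `2+`). ASCII `-` is used rather than a typographic minus so
labels survive any downstream encoding.

## Geometry

All lengths are multiples of the standard bond length L = 1.5, a common
desktop-editor convention for molfile coordinates; fused rings use the
actual shared-bond length instead, so fusion onto imported structures with
non-standard scaling stays regular.

* **Sprouting.** Candidates are the existing bond directions rotated by
  every nonzero multiple of 30°. Each candidate is scored by its minimum
  angular separation from the existing bonds, capped at 120°; the best
  score wins and ties go to the smallest angle in [0°, 360°). The cap is
  what makes a single-substituted atom continue at 120° (zig-zag chains)
  rather than 180°; without it the maximizer would always pick the
  antipode. An isolated atom sprouts due east.
* **Fusion side.** The default ("less crowded") side of a bond is chosen by
  counting atoms within 2L of the bond midpoint on each side of the bond
  line; ties fall to the side with the greater perpendicular clearance,
  then to the left of a1→a2. The flip flag mirrors the constructed
  vertices across the bond line, point for point.
* **Vertex merging.** A constructed ring vertex within 0.25·L of an
  existing atom is merged onto it and duplicate bonds are suppressed. This
  is what makes repeated fusion build anthracene-like condensed systems
  instead of stacking coincident atoms. A degenerate but consistent corner
  follows from it: flipping a same-size ring onto a pristine host ring
  mirrors it exactly onto the host, every vertex merges, and the molecule
  is unchanged.
* **Spiro.** A regular polygon with one vertex on the anchor and its
  centre along the anchor's sprout direction.

Construction accuracy is closed-form (no iteration); tests assert every
edge at the intended length to 1e−6 relative and the flip mirror to 1e−9.

## Molfile V2000

The writer emits the fixed-width CTfile layout: 3 header lines (the program
stamp is a constant so output is byte-reproducible), counts line ending
`0999 V2000`, atom lines `%10.4f%10.4f%10.4f %-3s` with z = 0 and all
twelve trailing fields zero, bond lines `%3d%3d%3d%3d` (stereo 1 = up,
6 = down), charges only as `M  CHG` records (≤ 8 pairs per record; the
obsolete atom-block column is written as 0), `M  END`, LF endings (CRLF on
request). 999 atoms/bonds is a hard cap set by the three-digit counts
fields; exceeding it raises a capacity error rather than emitting a
malformed file.

The reader is tolerant where files in the wild vary: all three line-ending
conventions are normalized first; the legacy charge column is honoured but
any `M  CHG` record resets every legacy charge (the CTfile precedence
rule); query symbols pass through as symbols. Coordinates survive a
round-trip to the printed 1e−4; everything else is exact. Errors carry
1-based line numbers.

## Depiction

SVG 1.1, white background, black bonds, deterministic output. Visual
constants are fractions of the reference bond length (the median drawn
bond length, so imported molecules at odd scales still render sensibly):
font 0.6, double-bond offset 0.18, wedge half-width 0.15, label clearance
0.35. The fit transform maps the bounding box into the canvas minus margin,
centred, aspect preserved, y-axis flipped (model y up, SVG y down); a
single atom gets unit scale. Zoom is applied about the canvas centre and
the pan offset is in pixels — the headless equivalents of a viewer's
move/zoom controls. Bonds are grouped per-bond with `data-order` and
`data-stereo` attributes, which the tests use instead of parsing geometry.

## Randomized testing

The generator in `sketchmol.testing` draws molecules the way the engine
could have produced them: up to 50 atoms, element mix skewed to the organic
subset plus query symbols, ~15% charged atoms, a random spanning tree over
a random subset (leaving isolated atoms and hence fragments), extra edges,
and stereo marks on ~10% of single bonds. It emulates structural breadth
for round-trip and depiction testing; it does **not** emulate chemical
sanity (valences may be exceeded, geometry is random scatter), so passing
round-trip tests demonstrates serialization fidelity, not that the engine
draws chemically reasonable pictures of these molecules. Round-trip suites
use 500 molecules (200 in the unit suite), the sprout property 1000
configurations; both run in seconds.

## Known limitations

* No aromatic bond type 4, isotopes, radicals, R-groups, 3D coordinates,
  reactions, or SMILES; one connection table per document (fragments as a
  workaround).
* No automatic layout for connection tables without coordinates and no
  collision-avoiding relayout after edits.
* Changing the order of a stereo-marked bond is an error rather than a
  silent stereo reset — the convention is genuinely ambiguous, and failing
  loudly was preferred to guessing.
* The crowding heuristic considers atoms, not bonds crossing the region, so
  a fused ring can still overlap distant parts of a large molecule.
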