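"""Round-trip a molfile through the parser, including foreign line endings.

Web textareas deliver CRLF on some platforms and legacy files use bare CR;
the parser normalizes all three conventions to the same molecule.
"""

from sketchmol import Molecule, apply_script, parse_molfile, write_molfile

mol = apply_script(
    Molecule(),
    "template name=benzene\nset_element atom=0 symbol=N\nset_charge atom=0 delta=1\n",
)
text = write_molfile(mol)
print(text)

for label, variant in (
    ("LF  ", text),
    ("CRLF", text.replace("\n", "\r\n")),
    ("CR  ", text.replace("\n", "\r")),
):
    back = parse_molfile(variant).molecule
    same = back.same_structure(mol, coord_tol=1e-4)
    print(f"{label} round-trip identical: {same}")

# The charged ring nitrogen is carried by the "M  CHG" record, not the
# obsolete atom-block column, and survives every line-ending convention.
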