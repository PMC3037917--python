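"""Sketch a small molecule from scratch and export it as a V2000 molfile.

Builds 4-aminophenol the way a user would click it together: stamp a
benzene template, turn one vertex into an OH and the opposite one into an
NH2 (both appear automatically from the free-valence label rules), then
print the molfile.
"""

from sketchmol import Molecule, apply_script, atom_label, write_molfile

mol = apply_script(
    Molecule(),
    """
    template name=benzene
    add_atom symbol=O attach=0     # phenol oxygen, sprouted at bond length
    add_atom symbol=N attach=3     # para amine
    """,
)

print("atom labels (empty = bare carbon vertex):")
for atom in mol.atoms:
    print(f"  atom {atom.id}: {atom.symbol:>2} -> {atom_label(mol, atom.id) or '(vertex)'}")

print()
print(write_molfile(mol))

# The O and N labels read OH and NH2: the oxygen has one bond and one free
# valence, the nitrogen one bond and two.  The molfile lists 8 atoms and
# 8 bonds, with the benzene template's three double bonds in the bond block.
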