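"""Depict a molecule as SVG: labels, double bonds, a stereo wedge, zoom.

Draws (S)-alaninol-like connectivity — a carbon with an OH arm, an NH2
arm and a wedge-marked methyl — and reports what ended up in the SVG.
"""

from xml.etree import ElementTree as ET

from sketchmol import Molecule, Stereo, apply_script, render_svg, set_stereo

mol = apply_script(
    Molecule(),
    """
    add_atom symbol=C
    add_atom symbol=C attach=0
    add_atom symbol=O attach=1
    add_atom symbol=N attach=0
    add_atom symbol=C attach=0
    """,
)
mol = set_stereo(mol, mol.bond_between(0, 4).id, Stereo.UP)

svg = render_svg(mol, width=400, height=300, zoom=1.0)
print(svg[:120] + "...\n")

ns = "{http://www.w3.org/2000/svg}"
root = ET.fromstring(svg)
labels = [t.text for t in root.findall(f".//{ns}text")]
wedges = root.findall(f".//{ns}polygon")
print(f"text labels: {labels}")
print(f"filled wedge polygons: {len(wedges)}")

# Only the heteroatoms get labels (OH, NH2); every bonded, uncharged
# carbon — including the wedge-marked methyl — is a bare vertex.  The
# wedge bond is a single filled triangle, narrow end at the stereocentre.
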