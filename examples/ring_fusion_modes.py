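"""The three modifier-flag editing behaviours, as atom/bond bookkeeping.

A ring template dropped on an existing ring can share a bond (fused), an
atom (spiro) or nothing (attached through a single bond); the shift flag
switches atom-target mode to spiro and mirrors bond-target fusion to the
other side of the bond.  Deleting a bond normally sweeps up orphaned
atoms; keep_orphans retains them as disconnected fragments (how salts are
drawn in a single connection table).
"""

from sketchmol import (
    Molecule,
    add_template,
    delete_bond,
    fragment_count,
    add_atom,
)

host = add_template(Molecule(), "cyclohexane")
print(f"host ring:          {len(host):2d} atoms, {len(host.bonds):2d} bonds")

fused = add_template(host, "cyclohexane", target_bond=host.bonds[0].id)
print(f"fused (decalin):    {len(fused):2d} atoms, {len(fused.bonds):2d} bonds")

spiro = add_template(host, "cyclohexane", target_atom=host.atoms[0].id, shift=True)
print(f"spiro:              {len(spiro):2d} atoms, {len(spiro.bonds):2d} bonds")

bonded = add_template(host, "cyclohexane", target_atom=host.atoms[0].id)
print(f"bonded (biphenyl-like): {len(bonded)} atoms, {len(bonded.bonds)} bonds")

# orphan handling on bond deletion
ethane = add_atom(Molecule(), "C")
ethane = add_atom(ethane, "C", attach_to=ethane.atoms[0].id)
swept = delete_bond(ethane, ethane.bonds[0].id)
kept = delete_bond(ethane, ethane.bonds[0].id, keep_orphans=True)
print()
print(f"ethane minus bond, orphans swept: {len(swept)} atoms")
print(f"ethane minus bond, orphans kept:  {len(kept)} atoms in "
      f"{fragment_count(kept)} fragments")

# Two 6-rings sharing a bond have 6+6-2 = 10 atoms and 6+6-1 = 11 bonds;
# sharing an atom (spiro) 11 and 12; joined by a new single bond 12 and 13.
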