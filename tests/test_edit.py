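"""Drawing primitives and edit scripts, including the modifier-key behaviours."""

import math

import pytest

from sketchmol import edit
from sketchmol.edit import EditScript, ScriptError, apply_script
from sketchmol.geometry import BOND_LENGTH, TEMPLATES
from sketchmol.model import (
    Molecule,
    SketchError,
    Stereo,
    atom_label,
    fragment_count,
    implicit_hydrogen_count,
)


class TestAddDeleteAtom:
    def test_add_to_empty_canvas(self):
        mol = edit.add_atom(Molecule(), "C")
        assert len(mol) == 1 and mol.bonds == []
        assert (mol.atoms[0].x, mol.atoms[0].y) == (0.0, 0.0)

    def test_sprouted_atom_at_standard_bond_length(self):
        mol = edit.add_atom(Molecule(), "C")
        mol = edit.add_atom(mol, "O", attach_to=mol.atoms[0].id)
        assert len(mol) == 2 and len(mol.bonds) == 1
        a, b = mol.atoms
        assert math.dist((a.x, a.y), (b.x, b.y)) == pytest.approx(BOND_LENGTH)

    def test_explicit_hydrogen_consumes_an_implicit_one(self):
        mol = edit.add_atom(Molecule(), "N")
        nid = mol.atoms[0].id
        assert implicit_hydrogen_count(mol, nid) == 3
        mol = edit.add_atom(mol, "H", attach_to=nid)
        assert implicit_hydrogen_count(mol, nid) == 2
        assert any(a.symbol == "H" for a in mol.atoms)

    def test_delete_ring_atom_opens_ring(self, benzene):
        out = edit.delete_atom(benzene, benzene.atoms[0].id)
        assert len(out) == 5 and len(out.bonds) == 4

    def test_delete_only_atom_empties_molecule(self):
        mol = edit.add_atom(Molecule(), "C")
        out = edit.delete_atom(mol, mol.atoms[0].id)
        assert len(out) == 0

    def test_delete_hub_of_star_leaves_isolated_atoms(self):
        mol = edit.add_atom(Molecule(), "C")
        hub = mol.atoms[0].id
        for _ in range(3):
            mol = edit.add_atom(mol, "C", attach_to=hub)
        out = edit.delete_atom(mol, hub)
        assert len(out) == 3 and out.bonds == []
        assert fragment_count(out) == 3

    def test_input_molecule_is_never_mutated(self, benzene):
        before = benzene.copy()
        edit.delete_atom(benzene, benzene.atoms[0].id)
        edit.add_atom(benzene, "N", attach_to=benzene.atoms[2].id)
        assert benzene.same_structure(before)


class TestAddDeleteBond:
    def test_close_chain_into_ring(self):
        mol = edit.add_atom(Molecule(), "C")
        for _ in range(5):
            mol = edit.add_atom(mol, "C", attach_to=mol.atoms[-1].id)
        assert len(mol.bonds) == 5
        mol = edit.add_bond(mol, mol.atoms[0].id, mol.atoms[-1].id)
        assert len(mol.bonds) == 6

    def test_duplicate_bond_is_an_error(self, benzene):
        b = benzene.bonds[0]
        with pytest.raises(SketchError):
            edit.add_bond(benzene, b.a1, b.a2)

    def test_triple_bond_drops_carbon_hydrogens(self):
        mol, ids = Molecule(), []
        for k in range(2):
            ids.append(mol.new_atom("C", 1.5 * k, 0.0).id)
        out = edit.add_bond(mol, ids[0], ids[1], order=3)
        assert implicit_hydrogen_count(out, ids[0]) == 1
        assert implicit_hydrogen_count(out, ids[1]) == 1

    def test_delete_both_endpoints_orphaned(self):
        mol, ids = Molecule(), []
        for k in range(2):
            ids.append(mol.new_atom("C", 1.5 * k, 0.0).id)
        bond = mol.new_bond(*ids)
        assert len(edit.delete_bond(mol, bond.id)) == 0

    def test_keep_orphans_creates_fragments(self):
        mol, ids = Molecule(), []
        for k in range(2):
            ids.append(mol.new_atom("C", 1.5 * k, 0.0).id)
        bond = mol.new_bond(*ids)
        out = edit.delete_bond(mol, bond.id, keep_orphans=True)
        assert len(out) == 2 and out.bonds == []
        assert fragment_count(out) == 2

    def test_ring_bond_deletion_orphans_nobody(self, benzene):
        out = edit.delete_bond(benzene, benzene.bonds[0].id)
        assert len(out) == 6 and len(out.bonds) == 5


class TestFieldSetters:
    def test_cycle_has_period_three(self, benzene):
        bond = benzene.bonds[0]
        assert bond.order == 1
        m = benzene
        for expected in (2, 3, 1):
            m = edit.set_bond_order(m, bond.id, "cycle")
            assert m.bond(bond.id).order == expected

    def test_charge_increment_builds_ammonium_label(self):
        mol = edit.add_atom(Molecule(), "N")
        out = edit.set_charge(mol, mol.atoms[0].id, +1)
        assert atom_label(out, out.atoms[0].id) == "NH4+"

    def test_stereo_on_double_bond_is_an_error(self, benzene):
        double = next(b for b in benzene.bonds if b.order == 2)
        with pytest.raises(SketchError):
            edit.set_stereo(benzene, double.id, Stereo.UP)

    def test_raising_order_of_stereo_bond_is_an_error(self, benzene):
        single = next(b for b in benzene.bonds if b.order == 1)
        marked = edit.set_stereo(benzene, single.id, Stereo.UP)
        with pytest.raises(SketchError):
            edit.set_bond_order(marked, single.id, 2)

    def test_set_element_relabels(self, benzene):
        out = edit.set_element(benzene, benzene.atoms[0].id, "N")
        assert atom_label(out, out.atoms[0].id) == "N"

    def test_charge_out_of_range(self):
        mol = edit.add_atom(Molecule(), "C")
        with pytest.raises(SketchError):
            edit.set_charge_value(mol, mol.atoms[0].id, 16)


def host_ring(name):
    return edit.add_template(Molecule(), name)


class TestTemplates:
    def test_free_benzene_alternates(self):
        mol = host_ring("benzene")
        assert len(mol) == 6 and len(mol.bonds) == 6
        orders = [b.order for b in mol.bonds]
        assert sorted(orders) == [1, 1, 1, 2, 2, 2]
        # alternation around the ring: no two adjacent bonds both double
        by_pair = {frozenset((b.a1, b.a2)): b.order for b in mol.bonds}
        for atom in mol.atoms:
            incident = [o for pair, o in by_pair.items() if atom.id in pair]
            assert sorted(incident) == [1, 2]

    @pytest.mark.parametrize("host", ["cyclohexane", "cyclopentane"])
    @pytest.mark.parametrize("name", sorted(TEMPLATES))
    def test_closed_form_counts(self, host, name):
        base = host_ring(host)
        n1, b1 = len(base), len(base.bonds)
        n2 = TEMPLATES[name].size
        fused = edit.add_template(base, name, target_bond=base.bonds[0].id)
        assert (len(fused), len(fused.bonds)) == (n1 + n2 - 2, b1 + n2 - 1)
        spiro = edit.add_template(
            base, name, target_atom=base.atoms[0].id, shift=True
        )
        assert (len(spiro), len(spiro.bonds)) == (n1 + n2 - 1, b1 + n2)
        bonded = edit.add_template(base, name, target_atom=base.atoms[0].id)
        assert (len(bonded), len(bonded.bonds)) == (n1 + n2, b1 + n2 + 1)

    @pytest.mark.parametrize("host", ["cyclohexane", "cyclopentane"])
    @pytest.mark.parametrize("name", sorted(TEMPLATES))
    def test_flip_mirrors_the_fused_ring(self, host, name):
        # the flipped ring is the mirror image of the default one across
        # the shared bond's line; mirrored vertices that land on existing
        # host atoms are merged onto them rather than duplicated
        from sketchmol.geometry import BOND_LENGTH, MERGE_RADIUS_FACTOR, reflect_point

        base = host_ring(host)
        bond = base.bonds[1]
        plain = edit.add_template(base, name, target_bond=bond.id)
        flipped = edit.add_template(base, name, target_bond=bond.id, shift=True)
        a1, a2 = base.atom(bond.a1), base.atom(bond.a2)
        mirrored = [
            reflect_point((a.x, a.y), (a1.x, a1.y), (a2.x, a2.y))
            for a in plain.atoms[len(base):]
        ]
        merge_r = MERGE_RADIUS_FACTOR * BOND_LENGTH
        expected_new = [
            p for p in mirrored
            if all(math.dist(p, (b.x, b.y)) > merge_r for b in base.atoms)
        ]
        new_flip = [(a.x, a.y) for a in flipped.atoms[len(base):]]
        assert len(new_flip) == len(expected_new)
        for p, q in zip(expected_new, new_flip):
            assert math.dist(p, q) < 1e-9

    def test_fused_ring_count_uses_existing_atoms(self, cyclohexane):
        fused = edit.add_template(
            cyclohexane, "cyclohexane", target_bond=cyclohexane.bonds[0].id
        )
        assert fragment_count(fused) == 1

    def test_all_new_edges_standard_length(self, cyclohexane):
        out = edit.add_template(
            cyclohexane, "cyclohexane", target_atom=cyclohexane.atoms[0].id
        )
        for b in out.bonds:
            a1, a2 = out.atom(b.a1), out.atom(b.a2)
            d = math.dist((a1.x, a1.y), (a2.x, a2.y))
            assert d == pytest.approx(BOND_LENGTH, rel=1e-6)

    def test_unknown_template(self):
        with pytest.raises(ScriptError):
            edit.add_template(Molecule(), "cyclononane")


class TestEditScripts:
    def test_empty_script_is_identity(self, benzene):
        out = apply_script(benzene, "")
        assert out.same_structure(benzene)

    def test_template_then_heteroatom_substitution(self):
        out = apply_script(
            Molecule(),
            "template name=benzene\nset_element atom=0 symbol=N\n",
        )
        labels = [atom_label(out, a.id) for a in out.atoms]
        assert labels.count("N") == 1
        assert labels.count("") == 5

    def test_unknown_verb_is_a_parse_error_with_line(self):
        with pytest.raises(ScriptError, match="line 2.*frobnicate"):
            EditScript.parse("template name=benzene\nfrobnicate atom=1\n")

    def test_comments_and_blank_lines_ignored(self):
        script = EditScript.parse(
            "# build a ring\n\ntemplate name=cyclohexane  # six carbons\n"
        )
        assert len(script.commands) == 1

    def test_failing_command_aborts_whole_script(self, benzene):
        before = benzene.copy()
        with pytest.raises(ScriptError, match="line 2"):
            apply_script(
                benzene,
                "set_element atom=0 symbol=O\ndelete_atom atom=999\n",
            )
        assert benzene.same_structure(before)

    def test_deterministic_replay(self):
        script = (
            "template name=cyclohexane\n"
            "template name=benzene bond=0\n"
            "add_atom symbol=O attach=3\n"
            "set_charge atom=3 delta=-1\n"
            "delete_bond bond=1 keep_orphans=true\n"
        )
        a = apply_script(Molecule(), script)
        b = apply_script(Molecule(), script)
        assert a.same_structure(b)
        assert [x.id for x in a.atoms] == [x.id for x in b.atoms]

    def test_shift_flag_reaches_the_operations(self):
        plain = apply_script(
            Molecule(),
            "template name=cyclohexane\ntemplate name=cyclohexane bond=0\n",
        )
        assert (len(plain), len(plain.bonds)) == (10, 11)
        # flipped onto a pristine host the mirror ring coincides with the
        # host ring itself, so every vertex merges and nothing is added —
        # distinct from the default side, which proves the flag is plumbed
        flipped = apply_script(
            Molecule(),
            "template name=cyclohexane\ntemplate name=cyclohexane bond=0 shift=true\n",
        )
        assert (len(flipped), len(flipped.bonds)) == (6, 6)
        spiro = apply_script(
            Molecule(),
            "template name=cyclohexane\ntemplate name=cyclohexane atom=0 shift=true\n",
        )
        assert (len(spiro), len(spiro.bonds)) == (11, 12)

    def test_bond_lookup_by_atom_pair(self):
        out = apply_script(
            Molecule(),
            "template name=cyclohexane\nset_bond_order a1=0 a2=1 order=2\n",
        )
        assert out.bond_between(0, 1).order == 2
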