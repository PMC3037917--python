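"""Drawing primitives as pure molecule -> molecule operations.

Each operation copies its input, applies one edit and returns the copy, so
an edit script replays deterministically and a failing command leaves the
caller's molecule untouched.

The interactive editor these operations come from used the Shift key to
modify three behaviours; here the modifier is an explicit flag:

* ring template on a bond — fused on the less crowded side, ``shift=True``
  flips the new ring to the opposite side;
* ring template on an atom — attached through a single bond,
  ``shift=True`` makes it a spiro ring sharing that atom;
* bond deletion — orphaned endpoints are removed, ``keep_orphans=True``
  preserves them, which is how disconnected structures (salts) are drawn
  inside the single connection table.
"""

from __future__ import annotations

import logging
import math
import shlex
from dataclasses import dataclass, field

from . import geometry
from .geometry import BOND_LENGTH, MERGE_RADIUS_FACTOR, TEMPLATES, RingTemplate
from .model import Molecule, SketchError, Stereo

logger = logging.getLogger(__name__)


class ScriptError(SketchError):
    """Raised when an edit script fails to parse or a command fails."""


# -- atom / bond edits ----------------------------------------------------


def add_atom(
    mol: Molecule,
    symbol: str,
    attach_to: int | None = None,
    pos: tuple[float, float] | None = None,
) -> Molecule:
    """Add an atom; with ``attach_to`` it is sprouted from an existing atom
    at standard bond length along the least-crowded direction and joined by
    a single bond.  ``pos`` overrides the position (and is the only way to
    place a free atom somewhere other than the origin)."""
    out = mol.copy()
    if attach_to is None:
        x, y = pos if pos is not None else (0.0, 0.0)
        out.new_atom(symbol, x, y)
        return out
    anchor = out.atom(attach_to)
    if pos is None:
        angle = geometry.sprout_direction(out, attach_to)
        pos = (
            anchor.x + BOND_LENGTH * math.cos(angle),
            anchor.y + BOND_LENGTH * math.sin(angle),
        )
    atom = out.new_atom(symbol, *pos)
    out.new_bond(attach_to, atom.id)
    return out


def delete_atom(mol: Molecule, atom_id: int) -> Molecule:
    out = mol.copy()
    out.remove_atom(atom_id)
    return out


def add_bond(mol: Molecule, a1: int, a2: int, order: int = 1) -> Molecule:
    out = mol.copy()
    out.new_bond(a1, a2, order)
    return out


def delete_bond(mol: Molecule, bond_id: int, keep_orphans: bool = False) -> Molecule:
    """Remove a bond; endpoints left without any bond ("orphans") are
    removed too unless ``keep_orphans`` is set."""
    out = mol.copy()
    bond = out.bond(bond_id)
    endpoints = (bond.a1, bond.a2)
    out.remove_bond(bond_id)
    if not keep_orphans:
        for a in endpoints:
            if out.degree(a) == 0:
                out.remove_atom(a)
    return out


def set_element(mol: Molecule, atom_id: int, symbol: str) -> Molecule:
    from .model import _check_symbol

    _check_symbol(symbol)
    out = mol.copy()
    out.atom(atom_id).symbol = symbol
    return out


def set_charge(mol: Molecule, atom_id: int, delta: int) -> Molecule:
    """Increment/decrement the formal charge (the editor's +/- buttons)."""
    out = mol.copy()
    atom = out.atom(atom_id)
    return set_charge_value(mol, atom_id, atom.charge + delta)


def set_charge_value(mol: Molecule, atom_id: int, charge: int) -> Molecule:
    from .model import MAX_CHARGE

    if not -MAX_CHARGE <= charge <= MAX_CHARGE:
        raise SketchError(f"charge {charge} outside [-{MAX_CHARGE}, +{MAX_CHARGE}]")
    out = mol.copy()
    out.atom(atom_id).charge = charge
    return out


def set_bond_order(mol: Molecule, bond_id: int, order: int | str) -> Molecule:
    """Set a bond's order, or cycle it 1 -> 2 -> 3 -> 1 with ``"cycle"``."""
    out = mol.copy()
    bond = out.bond(bond_id)
    if order == "cycle":
        order = bond.order % 3 + 1
    if order not in (1, 2, 3):
        raise SketchError(f"bond order must be 1, 2, 3 or 'cycle', got {order!r}")
    if bond.stereo is not Stereo.NONE and order != 1:
        raise SketchError("cannot raise the order of a stereo-marked bond")
    bond.order = order
    return out


def set_stereo(mol: Molecule, bond_id: int, stereo: Stereo) -> Molecule:
    out = mol.copy()
    bond = out.bond(bond_id)
    if stereo is not Stereo.NONE and bond.order != 1:
        raise SketchError("stereo marks apply to single bonds only")
    bond.stereo = stereo
    return out


# -- ring templates -------------------------------------------------------


def _resolve_template(template: RingTemplate | str) -> RingTemplate:
    if isinstance(template, RingTemplate):
        return template
    try:
        return TEMPLATES[template]
    except KeyError:
        raise ScriptError(f"unknown ring template {template!r}") from None


def _place_ring(
    mol: Molecule,
    coords: list[tuple[float, float]],
    existing: list[int],
    bond_orders: tuple[int, ...],
    merge_radius: float,
) -> list[int]:
    """Materialise a ring whose vertex cycle is ``existing`` atom ids
    followed by new vertices at ``coords``.  New vertices landing within
    ``merge_radius`` of an existing atom are merged onto it; bonds that
    already exist are kept as they are.  Returns the full cycle of ids."""
    ids = list(existing)
    for (x, y) in coords:
        merged = None
        for atom in mol.atoms:
            if math.dist((atom.x, atom.y), (x, y)) <= merge_radius:
                merged = atom.id
                break
        ids.append(merged if merged is not None else mol.new_atom("C", x, y).id)
    n = len(ids)
    for k in range(len(existing) - 1 if existing else 0, n):
        a, b = ids[k], ids[(k + 1) % n]
        if a != b and mol.bond_between(a, b) is None:
            mol.new_bond(a, b, bond_orders[k % len(bond_orders)])
    return ids


def add_template(
    mol: Molecule,
    template: RingTemplate | str,
    target_atom: int | None = None,
    target_bond: int | None = None,
    shift: bool = False,
    at: tuple[float, float] = (0.0, 0.0),
) -> Molecule:
    """Stamp a ring template onto the canvas, an atom, or a bond.

    * no target — free-standing carbon ring centred at ``at``;
    * ``target_atom`` — ring attached by one single bond (sprouted), or a
      spiro ring sharing the atom when ``shift`` is set;
    * ``target_bond`` — ring fused onto the bond (sharing its two atoms),
      erected on the less crowded side, or flipped across the bond line
      when ``shift`` is set.
    """
    tpl = _resolve_template(template)
    if target_atom is not None and target_bond is not None:
        raise SketchError("give at most one of target_atom and target_bond")
    out = mol.copy()

    if target_bond is not None:
        bond = out.bond(target_bond)
        coords = geometry.fuse_ring_coords(out, target_bond, tpl.size, flip=shift)
        shared_len = math.dist(
            (out.atom(bond.a1).x, out.atom(bond.a1).y),
            (out.atom(bond.a2).x, out.atom(bond.a2).y),
        )
        # shared bond plays the role of pattern edge 0 and keeps its order
        _place_ring(
            out,
            coords,
            [bond.a1, bond.a2][::-1],  # cycle a2 -> a1 closes via new path
            tpl.bond_orders,
            MERGE_RADIUS_FACTOR * shared_len,
        )
        return out

    if target_atom is not None:
        if shift:  # spiro: share exactly the anchor atom
            coords = geometry.spiro_ring_coords(out, target_atom, tpl.size)
            _place_ring(
                out, coords, [target_atom], tpl.bond_orders,
                MERGE_RADIUS_FACTOR * BOND_LENGTH,
            )
            return out
        # default: sprout a single bond, then a free ring at its end
        anchor = out.atom(target_atom)
        angle = geometry.sprout_direction(out, target_atom)
        ux, uy = math.cos(angle), math.sin(angle)
        first = (anchor.x + BOND_LENGTH * ux, anchor.y + BOND_LENGTH * uy)
        r = geometry.circumradius(tpl.size, BOND_LENGTH)
        center = (first[0] + r * ux, first[1] + r * uy)
        phase = math.atan2(first[1] - center[1], first[0] - center[0])
        coords = geometry.polygon_coords(tpl.size, BOND_LENGTH, center, phase)
        ids = _place_ring(
            out, coords, [], tpl.bond_orders, MERGE_RADIUS_FACTOR * BOND_LENGTH
        )
        if out.bond_between(target_atom, ids[0]) is None:
            out.new_bond(target_atom, ids[0])
        return out

    coords = geometry.polygon_coords(
        tpl.size, BOND_LENGTH, at, phase=math.pi / 2
    )
    _place_ring(out, coords, [], tpl.bond_orders, MERGE_RADIUS_FACTOR * BOND_LENGTH)
    return out


# -- edit scripts ---------------------------------------------------------


@dataclass
class Command:
    verb: str
    args: dict[str, str]
    line: int


@dataclass
class EditScript:
    """An ordered, replayable sequence of editing commands.

    Text form: one command per line, ``verb key=value ...``; blank lines
    and ``#`` comments are ignored.
    """

    commands: list[Command] = field(default_factory=list)

    @classmethod
    def parse(cls, text: str) -> "EditScript":
        commands = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = shlex.split(line)
            verb, args = parts[0], {}
            if verb not in _VERBS:
                raise ScriptError(f"line {lineno}: unknown verb {verb!r}")
            for part in parts[1:]:
                if "=" not in part:
                    raise ScriptError(
                        f"line {lineno}: expected key=value, got {part!r}"
                    )
                key, value = part.split("=", 1)
                args[key] = value
            commands.append(Command(verb, args, lineno))
        return cls(commands)


class _Args:
    """Typed accessors over a command's key=value map, with error context."""

    def __init__(self, cmd: Command):
        self.cmd = cmd
        self.unused = set(cmd.args)

    def _raw(self, key, default=None, required=False):
        if key in self.cmd.args:
            self.unused.discard(key)
            return self.cmd.args[key]
        if required:
            raise ScriptError(
                f"line {self.cmd.line}: {self.cmd.verb} needs {key}="
            )
        return default

    def text(self, key, default=None, required=False):
        return self._raw(key, default, required)

    def integer(self, key, default=None, required=False):
        raw = self._raw(key, default, required)
        if raw is None or isinstance(raw, int):
            return raw
        try:
            return int(raw)
        except ValueError:
            raise ScriptError(
                f"line {self.cmd.line}: {key}= must be an integer, got {raw!r}"
            ) from None

    def real(self, key, default=None, required=False):
        raw = self._raw(key, default, required)
        if raw is None or isinstance(raw, float):
            return raw
        try:
            return float(raw)
        except ValueError:
            raise ScriptError(
                f"line {self.cmd.line}: {key}= must be a number, got {raw!r}"
            ) from None

    def flag(self, key, default=False):
        raw = self._raw(key, default)
        if isinstance(raw, bool):
            return raw
        if raw.lower() in ("true", "yes", "1"):
            return True
        if raw.lower() in ("false", "no", "0"):
            return False
        raise ScriptError(
            f"line {self.cmd.line}: {key}= must be true or false, got {raw!r}"
        )

    def check_exhausted(self):
        if self.unused:
            extra = ", ".join(sorted(self.unused))
            raise ScriptError(
                f"line {self.cmd.line}: unknown argument(s) {extra} "
                f"for {self.cmd.verb}"
            )


def _arg_bond_id(mol: Molecule, a: _Args) -> int:
    bond_id = a.integer("bond")
    if bond_id is not None:
        return bond_id
    a1 = a.integer("a1", required=True)
    a2 = a.integer("a2", required=True)
    bond = mol.bond_between(a1, a2)
    if bond is None:
        raise ScriptError(
            f"line {a.cmd.line}: no bond between atoms {a1} and {a2}"
        )
    return bond.id


def _arg_pos(a: _Args) -> tuple[float, float] | None:
    x, y = a.real("x"), a.real("y")
    if x is None and y is None:
        return None
    return (x or 0.0, y or 0.0)


def _exec_add_atom(mol, a: _Args):
    return add_atom(
        mol, a.text("symbol", required=True), a.integer("attach"), _arg_pos(a)
    )


def _exec_delete_atom(mol, a: _Args):
    return delete_atom(mol, a.integer("atom", required=True))


def _exec_add_bond(mol, a: _Args):
    return add_bond(
        mol,
        a.integer("a1", required=True),
        a.integer("a2", required=True),
        a.integer("order", 1),
    )


def _exec_delete_bond(mol, a: _Args):
    return delete_bond(mol, _arg_bond_id(mol, a), a.flag("keep_orphans"))


def _exec_set_element(mol, a: _Args):
    return set_element(
        mol, a.integer("atom", required=True), a.text("symbol", required=True)
    )


def _exec_set_charge(mol, a: _Args):
    atom = a.integer("atom", required=True)
    value = a.integer("value")
    if value is not None:
        return set_charge_value(mol, atom, value)
    return set_charge(mol, atom, a.integer("delta", required=True))


def _exec_set_bond_order(mol, a: _Args):
    raw = a.text("order", required=True)
    if raw == "cycle":
        order: int | str = raw
    else:
        try:
            order = int(raw)
        except ValueError:
            raise ScriptError(
                f"line {a.cmd.line}: order= must be 1, 2, 3 or cycle, got {raw!r}"
            ) from None
    return set_bond_order(mol, _arg_bond_id(mol, a), order)


def _exec_set_stereo(mol, a: _Args):
    raw = a.text("stereo", required=True).upper()
    try:
        stereo = Stereo[raw]
    except KeyError:
        raise ScriptError(
            f"line {a.cmd.line}: stereo must be none, up or down, got {raw!r}"
        ) from None
    return set_stereo(mol, _arg_bond_id(mol, a), stereo)


def _exec_template(mol, a: _Args):
    return add_template(
        mol,
        a.text("name", required=True),
        target_atom=a.integer("atom"),
        target_bond=a.integer("bond"),
        shift=a.flag("shift"),
        at=_arg_pos(a) or (0.0, 0.0),
    )


def _exec_transform(mol, a: _Args):
    return geometry.transform(
        mol,
        translate=(a.real("dx", 0.0), a.real("dy", 0.0)),
        scale=a.real("scale", 1.0),
    )


_VERBS = {
    "add_atom": _exec_add_atom,
    "delete_atom": _exec_delete_atom,
    "add_bond": _exec_add_bond,
    "delete_bond": _exec_delete_bond,
    "set_element": _exec_set_element,
    "set_charge": _exec_set_charge,
    "set_bond_order": _exec_set_bond_order,
    "set_stereo": _exec_set_stereo,
    "template": _exec_template,
    "transform": _exec_transform,
}


def apply_script(mol: Molecule, script: EditScript | str) -> Molecule:
    """Replay an edit script against a molecule.

    Commands apply left to right.  The first failing command aborts the
    whole script with its error; since every operation is pure, the input
    molecule is never modified.
    """
    if isinstance(script, str):
        script = EditScript.parse(script)
    current = mol
    for cmd in script.commands:
        args = _Args(cmd)
        try:
            current = _VERBS[cmd.verb](current, args)
            args.check_exhausted()
        except ScriptError:
            raise
        except SketchError as exc:
            raise ScriptError(f"line {cmd.line}: {cmd.verb}: {exc}") from exc
        logger.debug("applied %s %s", cmd.verb, cmd.args)
    return current
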