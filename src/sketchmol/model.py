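"""Connection-table data model.

A :class:`Molecule` is a single connection table: an ordered list of atoms
(2D nodes with an element or query symbol and a formal charge) plus a list
of bonds (order 1-3, optional wedge/hash stereo mark).  Disconnected
fragments — salts, mixtures — live in the same table.

The module also implements the valence logic behind automatic atom labels:
the number of implicit hydrogens on an atom follows from its free valence,
so the displayed label ("NH2", "O-", ...) updates as bonds and charges
change around it.

Atom and bond identifiers are small integers that are stable under editing
and never reused, so edit scripts replay deterministically and molfile
export order is always insertion order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

from ._elements import ATOMIC_NUMBER, QUERY_SYMBOLS, VALENCE_LISTS

MAX_CHARGE = 15  # representable range of a V2000 "M  CHG" value


class SketchError(ValueError):
    """Base class for all domain errors raised by this package."""


class UnknownSymbolError(SketchError):
    def __init__(self, symbol: str):
        super().__init__(f"unknown atom symbol {symbol!r}")
        self.symbol = symbol


class Stereo(Enum):
    """Wedge mark on a single bond: plain, rising (wedge) or falling (hash)."""

    NONE = 0
    UP = 1
    DOWN = 6  # values match the V2000 bond-stereo codes


@dataclass
class Atom:
    id: int
    symbol: str
    x: float
    y: float
    charge: int = 0

    @property
    def is_query(self) -> bool:
        return self.symbol in QUERY_SYMBOLS


@dataclass
class Bond:
    id: int
    a1: int
    a2: int
    order: int = 1
    stereo: Stereo = Stereo.NONE

    def other(self, atom_id: int) -> int:
        return self.a2 if atom_id == self.a1 else self.a1


def _check_symbol(symbol: str) -> None:
    if symbol not in ATOMIC_NUMBER and symbol not in QUERY_SYMBOLS:
        raise UnknownSymbolError(symbol)


class Molecule:
    """One connection table; may hold several disconnected fragments."""

    def __init__(self) -> None:
        self._atoms: dict[int, Atom] = {}
        self._bonds: dict[int, Bond] = {}
        self._next_atom_id = 0
        self._next_bond_id = 0

    # -- access -----------------------------------------------------------

    @property
    def atoms(self) -> list[Atom]:
        """Atoms in insertion order (the molfile export order)."""
        return list(self._atoms.values())

    @property
    def bonds(self) -> list[Bond]:
        return list(self._bonds.values())

    def __len__(self) -> int:
        return len(self._atoms)

    def atom(self, atom_id: int) -> Atom:
        try:
            return self._atoms[atom_id]
        except KeyError:
            raise SketchError(f"no atom with id {atom_id}") from None

    def bond(self, bond_id: int) -> Bond:
        try:
            return self._bonds[bond_id]
        except KeyError:
            raise SketchError(f"no bond with id {bond_id}") from None

    def has_atom(self, atom_id: int) -> bool:
        return atom_id in self._atoms

    def bond_between(self, a1: int, a2: int) -> Bond | None:
        key = frozenset((a1, a2))
        for b in self._bonds.values():
            if frozenset((b.a1, b.a2)) == key:
                return b
        return None

    def incident_bonds(self, atom_id: int) -> list[Bond]:
        self.atom(atom_id)
        return [b for b in self._bonds.values() if atom_id in (b.a1, b.a2)]

    def neighbors(self, atom_id: int) -> list[int]:
        return [b.other(atom_id) for b in self.incident_bonds(atom_id)]

    def degree(self, atom_id: int) -> int:
        return len(self.incident_bonds(atom_id))

    def bond_order_sum(self, atom_id: int) -> int:
        return sum(b.order for b in self.incident_bonds(atom_id))

    # -- construction -----------------------------------------------------

    def new_atom(self, symbol: str, x: float, y: float, charge: int = 0) -> Atom:
        _check_symbol(symbol)
        if not (math.isfinite(x) and math.isfinite(y)):
            raise SketchError("atom coordinates must be finite")
        if not -MAX_CHARGE <= charge <= MAX_CHARGE:
            raise SketchError(
                f"charge {charge} outside [-{MAX_CHARGE}, +{MAX_CHARGE}]"
            )
        atom = Atom(self._next_atom_id, symbol, float(x), float(y), int(charge))
        self._atoms[atom.id] = atom
        self._next_atom_id += 1
        return atom

    def new_bond(
        self, a1: int, a2: int, order: int = 1, stereo: Stereo = Stereo.NONE
    ) -> Bond:
        if a1 == a2:
            raise SketchError("a bond must connect two distinct atoms")
        self.atom(a1), self.atom(a2)
        if self.bond_between(a1, a2) is not None:
            raise SketchError(f"atoms {a1} and {a2} are already bonded")
        if order not in (1, 2, 3):
            raise SketchError(f"bond order must be 1, 2 or 3, got {order!r}")
        if stereo is not Stereo.NONE and order != 1:
            raise SketchError("stereo marks apply to single bonds only")
        bond = Bond(self._next_bond_id, a1, a2, order, stereo)
        self._bonds[bond.id] = bond
        self._next_bond_id += 1
        return bond

    def remove_atom(self, atom_id: int) -> None:
        """Delete an atom together with all incident bonds."""
        self.atom(atom_id)
        for b in self.incident_bonds(atom_id):
            del self._bonds[b.id]
        del self._atoms[atom_id]

    def remove_bond(self, bond_id: int) -> None:
        self.bond(bond_id)
        del self._bonds[bond_id]

    def copy(self) -> "Molecule":
        m = Molecule()
        for a in self._atoms.values():
            m._atoms[a.id] = Atom(a.id, a.symbol, a.x, a.y, a.charge)
        for b in self._bonds.values():
            m._bonds[b.id] = Bond(b.id, b.a1, b.a2, b.order, b.stereo)
        m._next_atom_id = self._next_atom_id
        m._next_bond_id = self._next_bond_id
        return m

    # -- comparison -------------------------------------------------------

    def same_structure(self, other: "Molecule", coord_tol: float = 0.0) -> bool:
        """True if both tables agree in graph, symbols, charges, stereo and
        coordinates (within ``coord_tol``), comparing by position in the
        insertion order rather than by raw id."""
        if len(self._atoms) != len(other._atoms):
            return False
        if len(self._bonds) != len(other._bonds):
            return False
        index_self = {a.id: i for i, a in enumerate(self.atoms)}
        index_other = {a.id: i for i, a in enumerate(other.atoms)}
        for a, b in zip(self.atoms, other.atoms):
            if a.symbol != b.symbol or a.charge != b.charge:
                return False
            if abs(a.x - b.x) > coord_tol or abs(a.y - b.y) > coord_tol:
                return False
        edges_self = sorted(
            (
                tuple(sorted((index_self[b.a1], index_self[b.a2]))),
                b.order,
                b.stereo,
                index_self[b.a1],
            )
            for b in self.bonds
        )
        edges_other = sorted(
            (
                tuple(sorted((index_other[b.a1], index_other[b.a2]))),
                b.order,
                b.stereo,
                index_other[b.a1],
            )
            for b in other.bonds
        )
        return edges_self == edges_other


# -- valence model --------------------------------------------------------


# Elements that lose electrons from an incomplete shell (groups 1, 2 and
# 13): for these a negative charge adds binding capacity instead of
# removing it (borohydride B- binds four, a carbanion C- only three).
_EARLY_ELEMENTS = frozenset(
    {"Li", "Be", "Na", "Mg", "Al", "K", "Ca", "Ga", "Rb", "Sr", "In",
     "Cs", "Ba", "Tl", "B"}
)


def free_valence(symbol: str, charge: int, order_sum: int) -> int:
    """Remaining binding capacity of an atom with the given bond-order sum.

    The lowest standard valence state that accommodates the existing bonds
    is used, so hypervalent states come into play only when needed (sulfur
    with three single bonds is read as S(IV) with one free valence).
    Charge is folded in the way mainstream editors and toolkits do:

    * a cation is treated as isoelectronic with the element ``Z - charge``
      (N+ binds like carbon, Cl+ like sulfur);
    * an anion keeps its own valence ladder but each extra electron pair
      occupies one valence (O- has one bond left, S- climbs to S(IV) at
      two bonds) — except for the early elements, where the extra electron
      adds capacity (B- binds four).

    Atoms outside the tabulated main group have no free valence.
    """
    z = ATOMIC_NUMBER.get(symbol)
    if z is None:
        raise UnknownSymbolError(symbol)
    effective = order_sum
    if charge > 0:
        valences = VALENCE_LISTS.get(z - charge, ())
    else:
        valences = VALENCE_LISTS.get(z, ())
        if charge < 0:
            effective = order_sum + (charge if symbol in _EARLY_ELEMENTS else -charge)
    for valence in valences:
        if valence >= effective:
            return valence - effective
    return 0


def implicit_hydrogen_count(mol: Molecule, atom_id: int) -> int:
    """Hydrogens implied by the atom's free valence (shown in its label).

    Query atoms (A, Q, X) and explicit-hydrogen nodes never carry implicit
    hydrogens.  An atom whose bond-order sum exceeds every valence in its
    list is over-valent and gets zero.
    """
    atom = mol.atom(atom_id)
    if atom.is_query or atom.symbol == "H":
        return 0
    return free_valence(atom.symbol, atom.charge, mol.bond_order_sum(atom_id))


def charge_label(charge: int) -> str:
    """Superscript-style charge text: '', '+', '-', '2+', '3-', ..."""
    if charge == 0:
        return ""
    magnitude = "" if abs(charge) == 1 else str(abs(charge))
    return magnitude + ("+" if charge > 0 else "-")


def atom_label(mol: Molecule, atom_id: int) -> str:
    """Display label of an atom, updated automatically from its environment.

    Bonded, uncharged carbon is drawn as a bare vertex (empty label); every
    other atom shows its symbol, its implicit hydrogens ("NH2", "OH") and a
    trailing charge ("O-", "NH4+", magnitude first for multiple charges:
    "2+").  Query symbols render as themselves.
    """
    atom = mol.atom(atom_id)
    if atom.is_query:
        return atom.symbol
    if atom.symbol == "C" and atom.charge == 0 and mol.degree(atom_id) >= 1:
        return ""
    label = atom.symbol
    h = implicit_hydrogen_count(mol, atom_id)
    if h >= 1:
        label += "H" + (str(h) if h > 1 else "")
    return label + charge_label(atom.charge)


def fragment_count(mol: Molecule) -> int:
    """Number of connected components (0 for the empty molecule)."""
    unvisited = set(mol._atoms)
    adjacency: dict[int, list[int]] = {a: [] for a in unvisited}
    for b in mol.bonds:
        adjacency[b.a1].append(b.a2)
        adjacency[b.a2].append(b.a1)
    count = 0
    while unvisited:
        count += 1
        stack = [unvisited.pop()]
        while stack:
            for nb in adjacency[stack.pop()]:
                if nb in unvisited:
                    unvisited.remove(nb)
                    stack.append(nb)
    return count


def iter_fragments(mol: Molecule) -> Iterator[set[int]]:
    """Yield the atom-id sets of the connected components."""
    unvisited = set(mol._atoms)
    adjacency: dict[int, list[int]] = {a: [] for a in unvisited}
    for b in mol.bonds:
        adjacency[b.a1].append(b.a2)
        adjacency[b.a2].append(b.a1)
    while unvisited:
        component = set()
        stack = [unvisited.pop()]
        while stack:
            a = stack.pop()
            component.add(a)
            for nb in adjacency[a]:
                if nb in unvisited:
                    unvisited.remove(nb)
                    stack.append(nb)
        yield component
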