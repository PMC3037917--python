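"""2D coordinate generation for sketching.

Everything a structure editor needs to place atoms without a mouse:
regular-polygon ring templates, the sprout direction for a new substituent
(least-crowded 30-degree grid angle), ring fusion onto an existing bond
(with an optional flip to the other side), spiro attachment at an atom, and
the move/zoom affine transform used by depiction.

All angles are radians; coordinates are unitless molfile coordinates with a
standard bond length of 1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import Molecule, SketchError

#: Standard bond length in coordinate units.  Molfile coordinates carry no
#: physical unit; 1.5 matches common desktop-editor output.
BOND_LENGTH = 1.5

#: Angular grid for sprout candidates (standard sketcher aesthetics).
SPROUT_GRID = math.pi / 6

#: A sprout angle is considered unconstrained once it clears its existing
#: neighbours by 120 degrees; among equally clear candidates the smallest
#: angle wins, which yields conventional zig-zag chains (120 degrees off a
#: single bond rather than a straight 180-degree continuation).
_SEPARATION_CAP = 2 * math.pi / 3

#: New ring vertices landing within this fraction of the bond length of an
#: existing atom are merged onto it.
MERGE_RADIUS_FACTOR = 0.25

TWO_PI = 2 * math.pi


@dataclass(frozen=True)
class RingTemplate:
    """A named regular ring: size plus the bond-order pattern along it."""

    name: str
    size: int
    bond_orders: tuple[int, ...]

    def __post_init__(self):
        if len(self.bond_orders) != self.size:
            raise SketchError("bond-order pattern length must equal ring size")


def _plain(name: str, size: int) -> RingTemplate:
    return RingTemplate(name, size, (1,) * size)


#: The seven standard ring templates.
TEMPLATES: dict[str, RingTemplate] = {
    t.name: t
    for t in (
        _plain("cyclopropane", 3),
        _plain("cyclobutane", 4),
        _plain("cyclopentane", 5),
        _plain("cyclohexane", 6),
        RingTemplate("benzene", 6, (1, 2, 1, 2, 1, 2)),
        _plain("cycloheptane", 7),
        _plain("cyclooctane", 8),
    )
}


def circumradius(size: int, bond_length: float) -> float:
    """Circumradius of a regular ``size``-gon with the given side length."""
    return bond_length / (2 * math.sin(math.pi / size))


def polygon_coords(
    size: int,
    bond_length: float,
    center: tuple[float, float] = (0.0, 0.0),
    phase: float = 0.0,
) -> list[tuple[float, float]]:
    """Vertices of a regular polygon with a given side length.

    The first vertex sits at angle ``phase`` from ``center``; vertices
    proceed counter-clockwise.
    """
    if not 3 <= size <= 8:
        raise SketchError(f"ring size must be between 3 and 8, got {size}")
    if bond_length <= 0:
        raise SketchError("bond length must be positive")
    r = circumradius(size, bond_length)
    cx, cy = center
    return [
        (cx + r * math.cos(phase + k * TWO_PI / size),
         cy + r * math.sin(phase + k * TWO_PI / size))
        for k in range(size)
    ]


def _normalize_angle(a: float) -> float:
    a = math.fmod(a, TWO_PI)
    return a + TWO_PI if a < 0 else a


def _angular_separation(a: float, b: float) -> float:
    d = abs(_normalize_angle(a) - _normalize_angle(b))
    return min(d, TWO_PI - d)


def bond_directions(mol: Molecule, atom_id: int) -> list[float]:
    """Angles of the bonds leaving an atom, in [0, 2pi)."""
    a = mol.atom(atom_id)
    dirs = []
    for nb in mol.neighbors(atom_id):
        n = mol.atom(nb)
        dirs.append(_normalize_angle(math.atan2(n.y - a.y, n.x - a.x)))
    return dirs


def sprout_direction(mol: Molecule, atom_id: int) -> float:
    """Angle at which a new substituent should leave an atom.

    An unbonded atom sprouts due east.  Otherwise candidates are the
    existing bond directions rotated by every nonzero multiple of 30
    degrees; each is scored by its angular clearance from all existing
    bonds, capped at 120 degrees, and the best-scoring smallest angle wins.
    """
    dirs = bond_directions(mol, atom_id)
    if not dirs:
        return 0.0
    candidates = sorted(
        {
            round(_normalize_angle(d + k * SPROUT_GRID), 12)
            for d in dirs
            for k in range(1, 12)
        }
    )
    best_angle = 0.0
    best_score = -1.0
    for cand in candidates:
        score = min(
            _SEPARATION_CAP, min(_angular_separation(cand, d) for d in dirs)
        )
        if score > best_score + 1e-9:
            best_score = score
            best_angle = cand
    return best_angle


def reflect_point(
    p: tuple[float, float], a: tuple[float, float], b: tuple[float, float]
) -> tuple[float, float]:
    """Mirror ``p`` across the line through ``a`` and ``b``."""
    ax, ay = a
    ux, uy = b[0] - ax, b[1] - ay
    norm2 = ux * ux + uy * uy
    px, py = p[0] - ax, p[1] - ay
    t = (px * ux + py * uy) / norm2
    fx, fy = ax + t * ux, ay + t * uy  # foot of the perpendicular
    return (2 * fx - p[0], 2 * fy - p[1])


def _ring_on_bond(
    p1: tuple[float, float], p2: tuple[float, float], size: int, side: float
) -> list[tuple[float, float]]:
    """The size-2 free vertices of a regular polygon erected on segment
    p1-p2, on the side indicated by the sign of ``side`` (cross-product
    convention: +1 is to the left of p1->p2)."""
    d = math.dist(p1, p2)
    mx, my = (p1[0] + p2[0]) / 2, (p1[1] + p2[1]) / 2
    # unit normal pointing left of p1->p2
    nx, ny = -(p2[1] - p1[1]) / d, (p2[0] - p1[0]) / d
    sign = 1.0 if side >= 0 else -1.0
    apothem = d / (2 * math.tan(math.pi / size))
    cx, cy = mx + sign * apothem * nx, my + sign * apothem * ny
    r = circumradius(size, d)
    theta1 = math.atan2(p1[1] - cy, p1[0] - cx)
    step = TWO_PI / size
    # walk from p1 the long way round to p2
    rot = -sign * step  # direction that does NOT reach p2 in one step
    return [
        (cx + r * math.cos(theta1 + rot * k), cy + r * math.sin(theta1 + rot * k))
        for k in range(1, size - 1)
    ]


def fuse_ring_coords(
    mol: Molecule, bond_id: int, size: int, flip: bool = False
) -> list[tuple[float, float]]:
    """Coordinates of the new vertices of a ring fused onto an existing bond.

    The new ring shares the bond (an edge-fused, "condensed" system).  By
    default it is erected on the less crowded side of the bond line; with
    ``flip=True`` it is mirrored across that line to the other side.

    Returns the ``size - 2`` new vertex positions in path order from the
    bond's first atom towards its second.
    """
    if not 3 <= size <= 8:
        raise SketchError(f"ring size must be between 3 and 8, got {size}")
    bond = mol.bond(bond_id)
    a1, a2 = mol.atom(bond.a1), mol.atom(bond.a2)
    p1, p2 = (a1.x, a1.y), (a2.x, a2.y)
    d = math.dist(p1, p2)
    if d <= 0:
        raise SketchError("cannot fuse onto a zero-length bond")
    mx, my = (p1[0] + p2[0]) / 2, (p1[1] + p2[1]) / 2
    nx, ny = -(p2[1] - p1[1]) / d, (p2[0] - p1[0]) / d

    # Crowding census: atoms near the bond midpoint, split by side.
    counts = {1.0: 0, -1.0: 0}
    clearance = {1.0: math.inf, -1.0: math.inf}
    for atom in mol.atoms:
        if atom.id in (bond.a1, bond.a2):
            continue
        if math.dist((atom.x, atom.y), (mx, my)) > 2 * d:
            continue
        perp = (atom.x - mx) * nx + (atom.y - my) * ny
        side = 1.0 if perp >= 0 else -1.0
        counts[side] += 1
        clearance[side] = min(clearance[side], abs(perp))
    if counts[1.0] < counts[-1.0]:
        side = 1.0
    elif counts[-1.0] < counts[1.0]:
        side = -1.0
    elif clearance[1.0] > clearance[-1.0]:
        side = 1.0
    elif clearance[-1.0] > clearance[1.0]:
        side = -1.0
    else:
        side = 1.0
    if flip:
        side = -side
    return _ring_on_bond(p1, p2, size, side)


def spiro_ring_coords(
    mol: Molecule,
    atom_id: int,
    size: int,
    bond_length: float = BOND_LENGTH,
) -> list[tuple[float, float]]:
    """Coordinates of the new vertices of a spiro ring sharing one atom.

    The ring is a regular polygon with one vertex on the anchor atom and
    its centre along the anchor's sprout direction.  Returns the
    ``size - 1`` new vertex positions walking counter-clockwise from the
    anchor.
    """
    if not 3 <= size <= 8:
        raise SketchError(f"ring size must be between 3 and 8, got {size}")
    anchor = mol.atom(atom_id)
    direction = sprout_direction(mol, atom_id)
    r = circumradius(size, bond_length)
    cx = anchor.x + r * math.cos(direction)
    cy = anchor.y + r * math.sin(direction)
    phase = math.atan2(anchor.y - cy, anchor.x - cx)
    return polygon_coords(size, bond_length, (cx, cy), phase)[1:]


def transform(
    mol: Molecule, translate: tuple[float, float] = (0.0, 0.0), scale: float = 1.0
) -> Molecule:
    """Move/zoom: map every coordinate x -> scale*x + translate.

    The graph, symbols, charges and stereo marks are untouched.
    """
    if scale <= 0:
        raise SketchError(f"scale must be positive, got {scale}")
    out = mol.copy()
    tx, ty = translate
    for atom in out.atoms:
        atom.x = scale * atom.x + tx
        atom.y = scale * atom.y + ty
    return out
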