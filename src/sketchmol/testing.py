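"""Random connection-table generator for round-trip and property testing.

Molecules are drawn the way a sketcher could have produced them: a random
spanning tree plus a few extra edges, organic-subset elements with
occasional query symbols and formal charges, random bond orders, and
stereo marks on a fraction of the single bonds.
"""

from __future__ import annotations

import random

from .model import Molecule, Stereo

#: Element mix skewed towards the organic subset, plus query wildcards.
SYMBOL_POOL = (
    ["C"] * 12
    + ["N", "O"] * 3
    + ["S", "P", "F", "Cl", "Br", "I", "B", "Si", "H"]
    + ["A", "Q", "X"]
)


def random_molecule(
    rng: random.Random,
    max_atoms: int = 50,
    charge_fraction: float = 0.15,
    stereo_fraction: float = 0.1,
    query_atoms: bool = True,
) -> Molecule:
    """One random molecule with 1..max_atoms atoms, possibly disconnected."""
    pool = SYMBOL_POOL if query_atoms else [s for s in SYMBOL_POOL if s not in "AQX"]
    mol = Molecule()
    n = rng.randint(1, max_atoms)
    ids = []
    for _ in range(n):
        symbol = rng.choice(pool)
        charge = 0
        if rng.random() < charge_fraction:
            charge = rng.choice([-2, -1, -1, 1, 1, 2])
        atom = mol.new_atom(
            symbol,
            round(rng.uniform(-40.0, 40.0), 4),
            round(rng.uniform(-40.0, 40.0), 4),
            charge,
        )
        ids.append(atom.id)
    # spanning tree over a random fraction (leaving some atoms isolated
    # exercises the multi-fragment path), then a few extra edges
    rng.shuffle(ids)
    connect = ids[: max(1, int(len(ids) * rng.uniform(0.6, 1.0)))]
    for i in range(1, len(connect)):
        mol.new_bond(
            connect[i], rng.choice(connect[:i]), rng.choice((1, 1, 1, 2, 3))
        )
    for _ in range(rng.randint(0, max(0, n // 4))):
        a, b = rng.sample(ids, 2) if n >= 2 else (None, None)
        if a is not None and mol.bond_between(a, b) is None:
            mol.new_bond(a, b, rng.choice((1, 2)))
    for bond in mol.bonds:
        if bond.order == 1 and rng.random() < stereo_fraction:
            bond.stereo = rng.choice((Stereo.UP, Stereo.DOWN))
    return mol


def carbon_chain(n: int) -> Molecule:
    """A linear all-carbon chain of ``n`` atoms (zig-zag coordinates)."""
    from .geometry import BOND_LENGTH

    mol = Molecule()
    prev = None
    for i in range(n):
        x = i * BOND_LENGTH * 0.866
        y = (i % 2) * BOND_LENGTH * 0.5
        atom = mol.new_atom("C", x, y)
        if prev is not None:
            mol.new_bond(prev, atom.id)
        prev = atom.id
    return mol
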