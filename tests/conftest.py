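import random

import pytest
from hypothesis import settings as hypothesis_settings

from sketchmol import edit
from sketchmol.model import Molecule

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def benzene() -> Molecule:
    return edit.add_template(Molecule(), "benzene")


@pytest.fixture
def cyclohexane() -> Molecule:
    return edit.add_template(Molecule(), "cyclohexane")


@pytest.fixture
def cyclopentane() -> Molecule:
    return edit.add_template(Molecule(), "cyclopentane")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260929)


def build(symbols_bonds):
    """Tiny molecule builder: ([(symbol, charge), ...], [(i, j, order), ...])."""
    symbols, bonds = symbols_bonds
    mol = Molecule()
    ids = []
    for k, (symbol, charge) in enumerate(symbols):
        ids.append(mol.new_atom(symbol, 1.5 * k, 0.0, charge).id)
    for i, j, order in bonds:
        mol.new_bond(ids[i], ids[j], order)
    return mol, ids
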