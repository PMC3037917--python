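"""MDL molfile V2000 reader and writer.

The writer emits the fixed-width CTfile layout byte-reproducibly: three
header lines, the counts line ending in ``0999 V2000``, the atom block
(``%10.4f`` coordinates, z always 0.0000, symbol left-justified in three
columns), the bond block (atom indices, order, stereo code 1 = wedge up,
6 = hash down), charges as ``M  CHG`` records only, and ``M  END``.

The reader is tolerant: it accepts ``\\n``, ``\\r\\n`` and bare ``\\r``
line endings (web textareas and legacy Mac files deliver all three), reads
charges from both the obsolete atom-block column and ``M  CHG`` records —
the latter, when present, reset every legacy charge per the CTfile rule —
and passes the query symbols A, Q, X straight through.

The V2000 counts fields are three digits wide, which caps a connection
table at 999 atoms and 999 bonds; the writer enforces the cap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import Molecule, SketchError, Stereo

MAX_ATOMS = 999
MAX_BONDS = 999

#: Constant program stamp (second header line): byte-reproducible output.
PROGRAM_STAMP = "  sketchmol       2D"

_STEREO_TO_CODE = {Stereo.NONE: 0, Stereo.UP: 1, Stereo.DOWN: 6}
# code 4 ("either") has no model equivalent and is read as NONE
_CODE_TO_STEREO = {0: Stereo.NONE, 1: Stereo.UP, 4: Stereo.NONE, 6: Stereo.DOWN}

# obsolete atom-block charge column: 1..7 minus "doublet radical" code 4
_LEGACY_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}


class MolfileError(SketchError):
    """Malformed molfile text; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)
        self.line = line


class CapacityError(SketchError):
    """Connection table exceeds what the V2000 format can hold."""


@dataclass
class MolfileDocument:
    """A molecule plus the three free-text header lines of its molfile."""

    molecule: Molecule = field(default_factory=Molecule)
    title: str = ""
    program_stamp: str = PROGRAM_STAMP
    comment: str = ""


def normalize_line_endings(text: str) -> str:
    r"""Map ``\r\n``, ``\r`` and ``\n`` all to a single ``\n``."""
    return text.replace("\r\n", "\n").replace("\r", "\n")


# -- writing --------------------------------------------------------------


def write_molfile(doc: MolfileDocument | Molecule, crlf: bool = False) -> str:
    """Serialize to V2000 text (trailing newline included).

    Raises :class:`CapacityError` beyond 999 atoms or bonds.
    """
    if isinstance(doc, Molecule):
        doc = MolfileDocument(doc)
    mol = doc.molecule
    atoms = mol.atoms
    bonds = mol.bonds
    if len(atoms) > MAX_ATOMS:
        raise CapacityError(
            f"{len(atoms)} atoms exceed the V2000 limit of {MAX_ATOMS}"
        )
    if len(bonds) > MAX_BONDS:
        raise CapacityError(
            f"{len(bonds)} bonds exceed the V2000 limit of {MAX_BONDS}"
        )
    index = {a.id: i + 1 for i, a in enumerate(atoms)}  # 1-based file indices

    lines = [doc.title, doc.program_stamp, doc.comment]
    lines.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in atoms:
        if len(a.symbol) > 3:
            raise SketchError(f"symbol {a.symbol!r} too wide for the atom block")
        lines.append(
            f"{a.x:10.4f}{a.y:10.4f}{0.0:10.4f} {a.symbol:<3} 0" + "  0" * 11
        )
    for b in bonds:
        lines.append(
            f"{index[b.a1]:3d}{index[b.a2]:3d}{b.order:3d}"
            f"{_STEREO_TO_CODE[b.stereo]:3d}"
        )
    charged = [(index[a.id], a.charge) for a in atoms if a.charge != 0]
    for start in range(0, len(charged), 8):  # at most 8 pairs per record
        chunk = charged[start:start + 8]
        lines.append(
            f"M  CHG{len(chunk):3d}"
            + "".join(f"{i:4d}{c:4d}" for i, c in chunk)
        )
    lines.append("M  END")
    eol = "\r\n" if crlf else "\n"
    return eol.join(lines) + eol


# -- parsing --------------------------------------------------------------


def _int_field(text: str, what: str, lineno: int) -> int:
    try:
        return int(text.strip() or "0")
    except ValueError:
        raise MolfileError(f"bad {what} field {text.strip()!r}", lineno) from None


def _float_field(text: str, what: str, lineno: int) -> float:
    try:
        return float(text.strip())
    except ValueError:
        raise MolfileError(f"bad {what} field {text.strip()!r}", lineno) from None


def parse_molfile(text: str) -> MolfileDocument:
    """Parse V2000 text into a :class:`MolfileDocument`.

    Accepts any of the three common line-ending conventions.  Errors carry
    the offending line number.
    """
    lines = normalize_line_endings(text).split("\n")
    if len(lines) < 4:
        raise MolfileError("molfile needs 3 header lines and a counts line")
    counts = lines[3]
    if not counts.rstrip().endswith("V2000"):
        raise MolfileError(
            f"counts line does not end in V2000: {counts.rstrip()!r}", 4
        )
    n_atoms = _int_field(counts[0:3], "atom count", 4)
    n_bonds = _int_field(counts[3:6], "bond count", 4)
    if n_atoms < 0 or n_bonds < 0:
        raise MolfileError("negative counts", 4)

    mol = Molecule()
    ids = []
    first_atom_line = 5  # 1-based
    for i in range(n_atoms):
        lineno = first_atom_line + i
        if lineno - 1 >= len(lines):
            raise MolfileError("atom block truncated", lineno)
        line = lines[lineno - 1]
        if len(line) < 34:
            raise MolfileError(f"atom line too short: {line!r}", lineno)
        x = _float_field(line[0:10], "x coordinate", lineno)
        y = _float_field(line[10:20], "y coordinate", lineno)
        symbol = line[31:34].strip()
        if not symbol:
            raise MolfileError("empty atom symbol", lineno)
        legacy_code = _int_field(line[36:39], "charge", lineno) if len(line) >= 39 else 0
        charge = _LEGACY_CHARGE.get(legacy_code, 0)
        try:
            atom = mol.new_atom(symbol, x, y, charge)
        except SketchError as exc:
            raise MolfileError(str(exc), lineno) from exc
        ids.append(atom.id)

    first_bond_line = first_atom_line + n_atoms
    for i in range(n_bonds):
        lineno = first_bond_line + i
        if lineno - 1 >= len(lines):
            raise MolfileError("bond block truncated", lineno)
        line = lines[lineno - 1]
        if len(line) < 9:
            raise MolfileError(f"bond line too short: {line!r}", lineno)
        i1 = _int_field(line[0:3], "atom index", lineno)
        i2 = _int_field(line[3:6], "atom index", lineno)
        order = _int_field(line[6:9], "bond order", lineno)
        code = _int_field(line[9:12], "bond stereo", lineno) if len(line) >= 10 else 0
        for idx in (i1, i2):
            if not 1 <= idx <= n_atoms:
                raise MolfileError(
                    f"bond references atom {idx} of a {n_atoms}-atom block",
                    lineno,
                )
        stereo = _CODE_TO_STEREO.get(code, Stereo.NONE)
        if order == 1 and stereo is not Stereo.NONE:
            pass
        else:
            stereo = Stereo.NONE
        try:
            mol.new_bond(ids[i1 - 1], ids[i2 - 1], order, stereo)
        except SketchError as exc:
            raise MolfileError(str(exc), lineno) from exc

    # property block: scan for M CHG / M END
    saw_end = False
    saw_chg = False
    for offset, line in enumerate(lines[first_bond_line + n_bonds - 1:]):
        lineno = first_bond_line + n_bonds + offset
        if line.startswith("M  END"):
            saw_end = True
            break
        if line.startswith("M  CHG"):
            if not saw_chg:
                # CTfile rule: any M CHG record supersedes the whole
                # legacy charge column
                for atom in mol.atoms:
                    atom.charge = 0
                saw_chg = True
            fields = line[6:]
            n_pairs = _int_field(fields[0:3], "charge-pair count", lineno)
            for p in range(n_pairs):
                pair = fields[3 + 8 * p: 3 + 8 * (p + 1)]
                idx = _int_field(pair[0:4], "charge atom index", lineno)
                val = _int_field(pair[4:8], "charge value", lineno)
                if not 1 <= idx <= n_atoms:
                    raise MolfileError(
                        f"charge record references atom {idx}", lineno
                    )
                if not -15 <= val <= 15:
                    raise MolfileError(f"charge {val} out of range", lineno)
                mol.atom(ids[idx - 1]).charge = val
    if not saw_end:
        raise MolfileError("missing M  END", len(lines))

    title = lines[0] if len(lines) > 0 else ""
    stamp = lines[1] if len(lines) > 1 else ""
    comment = lines[2] if len(lines) > 2 else ""
    return MolfileDocument(mol, title, stamp, comment)
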