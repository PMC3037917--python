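"""Periodic-table data used by the connection-table model.

Only symbols and the standard valence lists of the main-group elements are
needed: the label logic computes implicit hydrogens from an atom's free
valence, and everything outside the organic main-group subset simply gets
no implicit hydrogens.
"""

from __future__ import annotations

# Symbols indexed by atomic number (index 0 unused).
SYMBOLS: tuple[str, ...] = (
    "",
    "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe",
    "Cs", "Ba",
    "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er",
    "Tm", "Yb", "Lu",
    "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra",
    "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr",
    "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds", "Rg", "Cn",
    "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

ATOMIC_NUMBER: dict[str, int] = {s: z for z, s in enumerate(SYMBOLS) if s}

# Wildcard symbols accepted in substructure queries:
#   A = any atom except H, Q = any atom except H and C, X = any halogen.
QUERY_SYMBOLS: frozenset[str] = frozenset({"A", "Q", "X"})

# Standard valence lists (lowest first) of the main-group elements, keyed by
# atomic number.  Hypervalent states of P, S, I and the noble gases are
# included so that e.g. a sulfur carrying three single bonds is read as an
# S(IV) centre with one free valence rather than an over-valent S(II).
VALENCE_LISTS: dict[int, tuple[int, ...]] = {
    1: (1,),            # H
    2: (0,),            # He
    3: (1,),            # Li
    4: (2,),            # Be
    5: (3,),            # B
    6: (4,),            # C
    7: (3,),            # N
    8: (2,),            # O
    9: (1,),            # F
    10: (0,),           # Ne
    11: (1,),           # Na
    12: (2,),           # Mg
    13: (3,),           # Al
    14: (4,),           # Si
    15: (3, 5),         # P
    16: (2, 4, 6),      # S
    17: (1,),           # Cl
    18: (0,),           # Ar
    19: (1,),           # K
    20: (2,),           # Ca
    31: (3,),           # Ga
    32: (4,),           # Ge
    33: (3, 5),         # As
    34: (2, 4, 6),      # Se
    35: (1,),           # Br
    36: (0,),           # Kr
    49: (3,),           # In
    50: (2, 4),         # Sn
    51: (3, 5),         # Sb
    52: (2, 4, 6),      # Te
    53: (1, 3, 5),      # I
    54: (0, 2, 4, 6),   # Xe
}
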