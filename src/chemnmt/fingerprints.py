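"""881-bit substructure-key fingerprints in the CACTVS/PubChem key layout.

The fingerprint is organised in the seven classical sections of the 881-bit
substructure-key design:

1. hierarchic element counts           (bits   0-114)
2. ring counts by size/type           (bits 115-262)
3. bonded element pairs               (bits 263-326)
4. simple atom nearest neighbours     (bits 327-415)
5. bond-order-specific atom pairs     (bits 416-459)
6. linear substructure SMARTS         (bits 460-712)
7. ring-substitution SMARTS           (bits 713-880)

This is an independent implementation of the key family built on RDKit
substructure matching: section semantics follow the published design, but
bit-for-bit identity with other toolkits is not guaranteed.  The fingerprint
is deterministic per structure and ignores stereochemistry, which is the
behaviour the round-trip evaluation relies on.
"""

from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem

N_BITS = 881

# -- section 1: hierarchic element counts -----------------------------------

_ELEMENT_COUNT_BITS: list[tuple[str, int]] = [
    ("H", 4), ("H", 8), ("H", 16), ("H", 32),
    ("Li", 1), ("Li", 2),
    ("B", 1), ("B", 2), ("B", 4),
    ("C", 2), ("C", 4), ("C", 8), ("C", 16), ("C", 32),
    ("N", 1), ("N", 2), ("N", 4), ("N", 8),
    ("O", 1), ("O", 2), ("O", 4), ("O", 8), ("O", 16),
    ("F", 1), ("F", 2), ("F", 4),
    ("Na", 1), ("Na", 2),
    ("Si", 1), ("Si", 2),
    ("P", 1), ("P", 2), ("P", 4),
    ("S", 1), ("S", 2), ("S", 4), ("S", 8),
    ("Cl", 1), ("Cl", 2), ("Cl", 4), ("Cl", 8),
    ("K", 1), ("K", 2),
    ("Br", 1), ("Br", 2), ("Br", 4),
    ("I", 1), ("I", 2), ("I", 4),
]
_SINGLE_ELEMENTS = (
    "Be Mg Al Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Rb Sr Y Zr Nb Mo "
    "Tc Ru Rh Pd Ag Cd In Sn Sb Te Cs Ba Lu Hf Ta W Re Os Ir Pt Au Hg Tl Pb "
    "Bi La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb U Pu Am"
).split()
_SECTION1_SIZE = 115

# -- section 2: ring counts --------------------------------------------------

# per ring size: how many count thresholds (>=1 ... >=k) are recorded
_RING_THRESHOLDS = {3: 2, 4: 2, 5: 5, 6: 5, 7: 2, 8: 2, 9: 1, 10: 1}
_RING_CATEGORIES = 6  # see _ring_category
_SECTION2_BASE = 115
_SECTION2_SIZE = 148

# -- section 3: bonded element pairs -----------------------------------------

_ATOM_PAIRS = [
    ("Li", "H"), ("Li", "Li"), ("Li", "B"), ("Li", "C"), ("Li", "O"),
    ("Li", "F"), ("Li", "P"), ("Li", "S"), ("Li", "Cl"),
    ("B", "H"), ("B", "B"), ("B", "C"), ("B", "N"), ("B", "O"), ("B", "F"),
    ("B", "Si"), ("B", "P"), ("B", "S"), ("B", "Cl"), ("B", "Br"),
    ("C", "H"), ("C", "C"), ("C", "N"), ("C", "O"), ("C", "F"), ("C", "Na"),
    ("C", "Mg"), ("C", "Al"), ("C", "Si"), ("C", "P"), ("C", "S"),
    ("C", "Cl"), ("C", "As"), ("C", "Se"), ("C", "Br"), ("C", "I"),
    ("N", "H"), ("N", "N"), ("N", "O"), ("N", "F"), ("N", "Si"), ("N", "P"),
    ("N", "S"), ("N", "Cl"), ("N", "Br"),
    ("O", "H"), ("O", "O"), ("O", "Mg"), ("O", "Na"), ("O", "Al"),
    ("O", "Si"), ("O", "P"), ("O", "K"),
    ("F", "P"), ("F", "S"),
    ("Al", "H"), ("Al", "Cl"),
    ("Si", "H"), ("Si", "Si"), ("Si", "Cl"),
    ("P", "H"), ("P", "P"),
    ("As", "H"), ("As", "As"),
]
_SECTION3_BASE = 263
_SECTION3_SIZE = 64


def _generate_neighbour_smarts() -> list[str]:
    """Section 4: central atom with a multiset of neighbour elements."""
    out: list[str] = []
    combos = {
        "C": ["C", "N", "O", "S", "F", "Cl", "Br"],
        "N": ["C", "N", "O"],
        "O": ["C", "N", "P", "S"],
        "S": ["C", "N", "O"],
        "P": ["C", "N", "O"],
    }
    for centre, nbrs in combos.items():
        for pair in itertools.combinations_with_replacement(nbrs, 2):
            out.append(f"[{centre}](~[{pair[0]}])~[{pair[1]}]")
        for trip in itertools.combinations_with_replacement(nbrs[:4], 3):
            out.append(
                f"[{centre}](~[{trip[0]}])(~[{trip[1]}])~[{trip[2]}]"
            )
    return out[:89]


def _generate_bond_pair_smarts() -> list[str]:
    """Section 5: element pairs with an explicit bond order."""
    out = []
    for a, b in [("C", "C"), ("C", "N"), ("C", "O"), ("C", "S"),
                 ("C", "P"), ("N", "N"), ("N", "O"), ("N", "S"),
                 ("O", "P"), ("O", "S"), ("S", "S"), ("N", "P")]:
        out.append(f"[{a}]-[{b}]")
        out.append(f"[{a}]=[{b}]")
    for a, b in [("C", "C"), ("C", "N"), ("N", "N")]:
        out.append(f"[{a}]#[{b}]")
    for a, b in [("c", "c"), ("c", "n"), ("n", "n"), ("c", "o"),
                 ("c", "s"), ("n", "o")]:
        out.append(f"[{a}]:[{b}]")
    return out[:44]


def _generate_linear_smarts() -> list[str]:
    """Section 6: linear three- and four-atom substructures."""
    atoms = ["C", "N", "O"]
    bonds = ["-", "=", "#"]
    out: list[str] = []
    for a, b1, b, b2, c in itertools.product(atoms, bonds, atoms, bonds,
                                             atoms):
        if b1 == "#" and b2 == "#":
            continue
        out.append(f"[{a}]{b1}[{b}]{b2}[{c}]")
    extra_atoms = ["S", "P", "F", "Cl", "Br", "I"]
    for x in extra_atoms:
        for a, b in itertools.product(atoms, atoms):
            out.append(f"[{x}]-[{a}]-[{b}]")
            out.append(f"[{x}]-[{a}]=[{b}]")
    for a, b, c, d in itertools.product(atoms, atoms, atoms, atoms):
        out.append(f"[{a}]-[{b}]-[{c}]-[{d}]")
    return out[:253]


def _generate_ring_smarts() -> list[str]:
    """Section 7: aromatic/saturated rings with substitution patterns."""
    out: list[str] = []
    subs = ["C", "N", "O", "S", "F", "Cl", "Br", "I"]
    for x in subs:
        out.append(f"[{x}]-c1ccccc1")
    for x, y in itertools.combinations_with_replacement(subs, 2):
        out.append(f"[{x}]-c1ccccc1-[{y}]")      # ortho
        out.append(f"[{x}]-c1cccc(c1)-[{y}]")    # meta
        out.append(f"[{x}]-c1ccc(cc1)-[{y}]")    # para
    for x in subs[:6]:
        out.append(f"[{x}]-c1ccncc1")
        out.append(f"[{x}]-c1ccccn1")
        out.append(f"[{x}]-C1CCCCC1")
        out.append(f"[{x}]-C1CCCC1")
    out.append("c1ccc2ccccc2c1")
    out.append("c1ccc2[nH]ccc2c1")
    out.append("c1ccc2occc2c1")
    out.append("c1ccc2sccc2c1")
    out.append("c1ccc2ncccc12")
    return out[:168]


_SECTION4_BASE, _SECTION4_SIZE = 327, 89
_SECTION5_BASE, _SECTION5_SIZE = 416, 44
_SECTION6_BASE, _SECTION6_SIZE = 460, 253
_SECTION7_BASE, _SECTION7_SIZE = 713, 168

_COMPILED: dict[str, list] = {}


def _compiled_patterns() -> dict[str, list]:
    if not _COMPILED:
        for key, gen in (
            ("s4", _generate_neighbour_smarts),
            ("s5", _generate_bond_pair_smarts),
            ("s6", _generate_linear_smarts),
            ("s7", _generate_ring_smarts),
        ):
            pats = []
            for smarts in gen():
                q = Chem.MolFromSmarts(smarts)
                if q is None:  # defensive; all patterns are static
                    continue
                pats.append(q)
            _COMPILED[key] = pats
    return _COMPILED


def _ring_category(mol: Chem.Mol, ring: tuple[int, ...]) -> tuple[int, bool]:
    """(category index 0..5, is_aromatic) for one SSSR ring.

    Categories: 0/1/2 = saturated-or-aromatic x (carbon-only / N-containing /
    other-heteroatom); 3/4/5 = the same for unsaturated non-aromatic rings.
    """
    atoms = [mol.GetAtomWithIdx(i) for i in ring]
    bonds = []
    for i, j in zip(ring, ring[1:] + ring[:1]):
        bonds.append(mol.GetBondBetweenAtoms(i, j))
    aromatic = all(b.GetIsAromatic() for b in bonds)
    unsaturated = (not aromatic) and any(
        b.GetBondType() != Chem.BondType.SINGLE for b in bonds
    )
    has_n = any(a.GetSymbol() == "N" for a in atoms)
    has_het = any(a.GetSymbol() not in ("C", "N") for a in atoms)
    if has_het:
        cat = 2
    elif has_n:
        cat = 1
    else:
        cat = 0
    if unsaturated:
        cat += 3
    return cat, aromatic


def substructure_keys(mol: Chem.Mol) -> np.ndarray:
    """Compute the 881-bit substructure-key vector for *mol*."""
    mol = Chem.Mol(mol)
    Chem.SanitizeMol(mol)
    molH = Chem.AddHs(mol)
    bits = np.zeros(N_BITS, dtype=np.uint8)

    # section 1: element counts
    counts: dict[str, int] = {}
    for atom in molH.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    pos = 0
    for element, threshold in _ELEMENT_COUNT_BITS:
        if counts.get(element, 0) >= threshold:
            bits[pos] = 1
        pos += 1
    for element in _SINGLE_ELEMENTS:
        if pos >= _SECTION1_SIZE:
            break
        if counts.get(element, 0) >= 1:
            bits[pos] = 1
        pos += 1

    # section 2: ring counts
    rings = [tuple(r) for r in Chem.GetSymmSSSR(mol)]
    by_size_cat: dict[tuple[int, int], int] = {}
    n_aromatic = 0
    n_het_aromatic = 0
    for ring in rings:
        size = len(ring)
        if not 3 <= size <= 10:
            continue
        cat, aromatic = _ring_category(mol, ring)
        by_size_cat[(size, cat)] = by_size_cat.get((size, cat), 0) + 1
        if aromatic:
            n_aromatic += 1
            if any(mol.GetAtomWithIdx(i).GetSymbol() != "C" for i in ring):
                n_het_aromatic += 1
    pos = _SECTION2_BASE
    for size in range(3, 11):
        for threshold in range(1, _RING_THRESHOLDS[size] + 1):
            for cat in range(_RING_CATEGORIES):
                if by_size_cat.get((size, cat), 0) >= threshold:
                    bits[pos] = 1
                pos += 1
    for k in range(1, 5):
        if n_aromatic >= k:
            bits[pos] = 1
        pos += 1
    for k in range(1, 5):
        if n_het_aromatic >= k:
            bits[pos] = 1
        pos += 1
    assert pos <= _SECTION3_BASE

    # section 3: bonded element pairs
    pairs = set()
    for bond in molH.GetBonds():
        a = bond.GetBeginAtom().GetSymbol()
        b = bond.GetEndAtom().GetSymbol()
        pairs.add((a, b))
        pairs.add((b, a))
    for offset, (a, b) in enumerate(_ATOM_PAIRS):
        if (a, b) in pairs:
            bits[_SECTION3_BASE + offset] = 1

    # sections 4-7: substructure SMARTS
    compiled = _compiled_patterns()
    for base, key in ((_SECTION4_BASE, "s4"), (_SECTION5_BASE, "s5"),
                      (_SECTION6_BASE, "s6"), (_SECTION7_BASE, "s7")):
        for offset, query in enumerate(compiled[key]):
            if mol.HasSubstructMatch(query):
                bits[base + offset] = 1
    return bits


def fingerprint_smiles(smiles: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return substructure_keys(mol)
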