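"""Rule-based IUPAC name -> structure parser.

A recursive-descent parser for a substantial, well-defined subset of
systematic organic nomenclature:

* substitutive names over acyclic hydrides (chains to C30, -ene/-yne
  unsaturation, the common suffixes -ol, -one, -al, -amine, -carboxylic acid,
  -carboxamide, -carbonitrile, esters named as "<alkyl> ...carboxylate/ -oate");
* monocyclic hydrides (``cyclo``), von Baeyer polycycles
  (``bicyclo[3.2.1]octane``, ``tetracyclo[8.7.1.0^2,7.0^14,18]octadecane`` --
  superscripts appear flattened, e.g. ``02,7``), skeletal replacement
  (``oxa``/``aza``/``thia``/``phospha`` with lambda-convention markers);
* a lexicon of retained ring systems with their fixed numbering (benzene,
  pyridine, pyrazole, quinoline, purine, 1,3-benzothiazole, ...);
* nested substituent prefixes with (), [] brackets and the multiplying
  prefixes di/tri/... and bis/tris/...;
* hydro prefixes and indicated hydrogen, resolved by re-deriving a valid
  double-bond assignment over the affected ring system;
* stereodescriptors, which are syntactically parsed and *validated* (the
  referenced locant must exist and be a plausible stereocentre) but not
  encoded in the output: downstream structure comparison uses substructure
  fingerprints, which are stereo-agnostic.

Errors are typed so that callers can report failure categories: unfindable
locants, valency violations, stereochemistry limitations, disconnected
names, double-bond assignment failures, and constructs outside the grammar.

The parser is deliberately independent of the package's structure-to-name
generator: it never consults the namer, so a successful round trip
(name -> structure -> canonical SMILES equality) is a genuine two-sided check.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem

from .corpus import canonicalize_mol


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class NameParseError(ValueError):
    """Base class: the name could not be converted to a structure."""

    category = "parse"

    def __init__(self, message: str, name: str | None = None):
        self.name = name
        super().__init__(message)


class LocantError(NameParseError):
    """A locant refers to an atom that does not exist in its fragment."""

    category = "locant"


class ValencyError(NameParseError):
    """The implied structure puts an atom in an impossible valency state."""

    category = "valency"


class StereoError(NameParseError):
    """A stereodescriptor is unsupported or refers to an impossible centre."""

    category = "stereo"


class DisconnectedNameError(NameParseError):
    """Names of disconnected (multi-component) species are not supported."""

    category = "disconnected"


class KekulizationError(NameParseError):
    """No valid double-bond assignment exists for the named ring system."""

    category = "double-bonds"


class UnsupportedNameError(NameParseError):
    """The name uses nomenclature outside the supported grammar."""

    category = "unsupported"


class SuffixError(NameParseError):
    """A suffix cannot be applied to the group it is attached to."""

    category = "suffix"


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

ALKANE_STEMS = {
    "meth": 1, "eth": 2, "prop": 3, "but": 4, "pent": 5, "hex": 6,
    "hept": 7, "oct": 8, "non": 9, "dec": 10, "undec": 11, "dodec": 12,
    "tridec": 13, "tetradec": 14, "pentadec": 15, "hexadec": 16,
    "heptadec": 17, "octadec": 18, "nonadec": 19, "icos": 20, "eicos": 20,
    "henicos": 21, "docos": 22, "tricos": 23, "tetracos": 24,
    "pentacos": 25, "hexacos": 26, "heptacos": 27, "octacos": 28,
    "nonacos": 29, "triacont": 30,
}
_STEMS_BY_LEN = sorted(ALKANE_STEMS, key=len, reverse=True)

MULTIPLIERS = {
    "di": 2, "tri": 3, "tetra": 4, "penta": 5, "hexa": 6, "hepta": 7,
    "octa": 8, "nona": 9, "deca": 10, "undeca": 11, "dodeca": 12,
}
KIS_MULTIPLIERS = {"bis": 2, "tris": 3, "tetrakis": 4, "pentakis": 5, "hexakis": 6}
_MULT_BY_LEN = sorted(MULTIPLIERS, key=len, reverse=True)

REPLACEMENT_ELEMENTS = {
    "oxa": "O", "thia": "S", "selena": "Se", "aza": "N",
    "phospha": "P", "sila": "Si", "bora": "B",
}

VON_BAEYER_PREFIXES = {
    "bicyclo": 2, "tricyclo": 3, "tetracyclo": 4,
    "pentacyclo": 5, "hexacyclo": 6, "heptacyclo": 7,
}

# Allowed total valences per element (charge-adjusted separately).
VALENCES = {
    "C": (4,), "N": (3,), "O": (2,), "S": (2, 4, 6), "P": (3, 5),
    "F": (1,), "Cl": (1,), "Br": (1,), "I": (1,), "Si": (4,),
    "B": (3,), "Se": (2, 4, 6), "H": (1,),
}


# ---------------------------------------------------------------------------
# Fragment: a partially built structure with named locants
# ---------------------------------------------------------------------------


@dataclass
class _Atom:
    element: str
    charge: int = 0
    lam: int | None = None  # lambda-convention valence, e.g. 5 for P(V)


@dataclass
class Fragment:
    atoms: list[_Atom] = field(default_factory=list)
    bonds: dict[tuple[int, int], int] = field(default_factory=dict)
    locants: dict[str, int] = field(default_factory=dict)
    attach: int | None = None
    ring_bonds: set[tuple[int, int]] = field(default_factory=set)
    broken_sp2: set[int] = field(default_factory=set)  # lost a ring double
    no_double: set[int] = field(default_factory=set)  # hydro / indicated H
    stereo_locants: list[str] = field(default_factory=list)

    # -- construction -------------------------------------------------------

    def add_atom(self, element: str, charge: int = 0, locant: str | None = None) -> int:
        self.atoms.append(_Atom(element, charge))
        idx = len(self.atoms) - 1
        if locant is not None:
            self.locants[locant] = idx
        return idx

    def _key(self, i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def add_bond(self, i: int, j: int, order: int = 1, ring: bool = False) -> None:
        key = self._key(i, j)
        if key in self.bonds:
            raise NameParseError(f"duplicate bond between atoms {i} and {j}")
        self.bonds[key] = order
        if ring:
            self.ring_bonds.add(key)

    def set_order(self, i: int, j: int, order: int) -> None:
        key = self._key(i, j)
        if key not in self.bonds:
            raise LocantError(
                f"no bond between positions for unsaturation ({i + 1},{j + 1})"
            )
        self.bonds[key] = order

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def bond_order_sum(self, i: int) -> int:
        return sum(o for (a, b), o in self.bonds.items() if a == i or b == i)

    def max_valence(self, i: int) -> int:
        atom = self.atoms[i]
        if atom.lam is not None:
            return atom.lam
        allowed = VALENCES.get(atom.element, (4,))
        base = max(allowed)
        if atom.element == "N" and atom.charge > 0:
            base = 4
        if atom.element in ("O", "S") and atom.charge > 0:
            base += 1
        return base

    def free_valence(self, i: int) -> int:
        return self.max_valence(i) - self.bond_order_sum(i)

    def resolve(self, locant: str) -> int:
        if locant not in self.locants:
            raise LocantError(f"could not find the atom with locant {locant}")
        return self.locants[locant]

    def merge(self, other: "Fragment") -> int:
        """Absorb *other*; returns the index offset of its atoms."""
        offset = len(self.atoms)
        self.atoms.extend(other.atoms)
        for (i, j), o in other.bonds.items():
            self.bonds[(i + offset, j + offset)] = o
        self.ring_bonds.update(
            (i + offset, j + offset) for (i, j) in other.ring_bonds
        )
        self.broken_sp2.update(i + offset for i in other.broken_sp2)
        self.no_double.update(i + offset for i in other.no_double)
        return offset

    # -- chemistry helpers --------------------------------------------------

    def strip_double(self, i: int) -> None:
        """Demote any double ring bond at atom *i*; partner becomes 'broken'."""
        for (a, b), o in list(self.bonds.items()):
            if o == 2 and i in (a, b) and (a, b) in self.ring_bonds:
                self.bonds[(a, b)] = 1
                partner = b if a == i else a
                self.broken_sp2.add(partner)
                self.broken_sp2.add(i)

    def default_attach_atom(self) -> int:
        one = self.locants.get("1")
        if one is not None and self.free_valence(one) >= 1:
            return one
        for i in range(len(self.atoms)):
            if self.free_valence(i) >= 1:
                return i
        raise ValencyError("no free valence left for substituent attachment")

    def attach_substituent(self, sub: "Fragment", site: int | None,
                           order: int = 1) -> None:
        if sub.attach is None:
            raise NameParseError("substituent has no attachment point")
        target = site if site is not None else self.default_attach_atom()
        if order == 2:
            self.strip_double(target)
            self.no_double.discard(target)
            self.broken_sp2.discard(target)
        elif self.free_valence(target) < order:
            # substitution at a fully bonded ring atom (e.g. purin-9-yl at a
            # nitrogen carrying a double bond) forces a tautomeric shift
            self.strip_double(target)
            self.no_double.add(target)
        offset = self.merge(sub)
        self.add_bond(target, sub.attach + offset, order)

    # -- finishing ----------------------------------------------------------

    def fix_double_bonds(self) -> None:
        """Re-derive a double-bond assignment after hydro/oxo perturbations.

        When a ring atom loses its double bond (a hydro prefix, an indicated
        hydrogen, a ``-one`` suffix), the remaining pi system may need a
        different Kekule assignment.  All ring doubles in the perturbed pool
        are cleared and re-derived as a matching: every affected carbon must
        regain exactly one double bond (unless explicitly saturated), while
        heteroatoms may instead carry an H.  Failure to cover a required
        carbon is reported as a double-bond assignment error.
        """
        if not self.broken_sp2:
            return
        # atoms participating in the original unsaturated ring system
        doubled = set()
        for (a, b), o in self.bonds.items():
            if o == 2 and (a, b) in self.ring_bonds:
                doubled.update((a, b))
        pool = doubled | set(self.broken_sp2)
        # clear ring doubles inside the pool, then reassign
        for (a, b), o in list(self.bonds.items()):
            if o == 2 and (a, b) in self.ring_bonds and a in pool and b in pool:
                self.bonds[(a, b)] = 1
        required, optional = set(), set()
        for i in pool:
            if i in self.no_double:
                continue
            if any(o == 2 for (a, b), o in self.bonds.items() if i in (a, b)):
                continue  # satisfied by an exocyclic double (e.g. C=O)
            fv = self.free_valence(i)
            if self.atoms[i].element == "C":
                if fv < 1:
                    raise KekulizationError(
                        "failed to assign all double bonds in the named "
                        "ring system"
                    )
                required.add(i)
            elif fv >= 1:
                optional.add(i)
        # a tautomeric shift may recruit a ring heteroatom that never held a
        # double bond (e.g. the NH of purine when N9 is substituted)
        ring_atoms = {a for bond in self.ring_bonds for a in bond}
        for i in ring_atoms - pool:
            if (self.atoms[i].element != "C" and i not in self.no_double
                    and self.free_valence(i) >= 1
                    and not any(o == 2 for (a, b), o in self.bonds.items()
                                if i in (a, b))):
                optional.add(i)
        eligible = required | optional
        edges = [
            (a, b) for (a, b) in self.ring_bonds
            if a in eligible and b in eligible and self.bonds[(a, b)] == 1
        ]
        best = self._match(required, eligible, edges)
        if best is None:
            raise KekulizationError(
                "failed to assign all double bonds in the named ring system"
            )
        for (a, b) in best:
            self.bonds[(a, b) if a < b else (b, a)] = 2

    def _match(self, required, pool, edges):
        adj: dict[int, list[int]] = {i: [] for i in pool}
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        req = set(required)
        order = sorted(req) + sorted(i for i in pool if i not in req)

        def search(idx: int, used: set[int], chosen):
            if idx == len(order):
                return chosen
            head = order[idx]
            if head in used:
                return search(idx + 1, used, chosen)
            for nb in adj[head]:
                if nb not in used:
                    res = search(idx + 1, used | {head, nb},
                                 chosen + [(head, nb)])
                    if res is not None:
                        return res
            if head in req:
                return None  # a required carbon cannot be matched
            return search(idx + 1, used, chosen)

        return search(0, set(), [])

    def to_mol(self) -> Chem.Mol:
        self.fix_double_bonds()
        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(atom.charge)
            rw.AddAtom(a)
        orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                  3: Chem.BondType.TRIPLE}
        for (i, j), o in self.bonds.items():
            rw.AddBond(i, j, orders[o])
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Chem.AtomValenceException as exc:
            raise ValencyError(f"atom in unphysical valency state: {exc}") from exc
        except Chem.KekulizeException as exc:
            raise KekulizationError(str(exc)) from exc
        except Exception as exc:  # other sanitisation problems
            raise NameParseError(f"structure failed sanitisation: {exc}") from exc
        return mol

    def validate_stereo(self) -> None:
        for loc in self.stereo_locants:
            if loc not in self.locants:
                raise StereoError(
                    f"stereodescriptor refers to missing locant {loc}"
                )
            idx = self.locants[loc]
            heavy = len(self.neighbors(idx))
            if self.attach == idx:
                heavy += 1  # the outward attachment bond is still pending
            if heavy < 3 and self.atoms[idx].element == "C":
                raise StereoError(
                    f"atom at locant {loc} cannot be a stereocentre "
                    f"(only {heavy} heavy neighbours)"
                )


def _chain(n: int) -> Fragment:
    frag = Fragment()
    prev = None
    for k in range(n):
        idx = frag.add_atom("C", locant=str(k + 1))
        if prev is not None:
            frag.add_bond(prev, idx)
        prev = idx
    return frag


def _ring_from_spec(labels: str, elements: str, bonds: str) -> Fragment:
    frag = Fragment()
    labs = labels.split()
    els = elements.split()
    for lab, el in zip(labs, els):
        frag.add_atom(el, locant=lab)
    for spec in bonds.split():
        if "=" in spec:
            a, b = spec.split("=")
            order = 2
        else:
            a, b = spec.split("-")
            order = 1
        frag.add_bond(frag.locants[a], frag.locants[b], order, ring=True)
    return frag


# Retained ring systems with their fixed numbering.  Bond strings give one
# valid Kekule assignment; the double-bond fixer handles tautomeric
# adjustments demanded by hydro prefixes, indicated hydrogen and -one
# suffixes.
_RING_SPECS: dict[str, tuple[str, str, str]] = {
    "benzene": ("1 2 3 4 5 6", "C C C C C C", "1=2 2-3 3=4 4-5 5=6 6-1"),
    "pyridine": ("1 2 3 4 5 6", "N C C C C C", "1=2 2-3 3=4 4-5 5=6 6-1"),
    "pyridazine": ("1 2 3 4 5 6", "N N C C C C", "1-2 2=3 3-4 4=5 5-6 6=1"),
    "pyrimidine": ("1 2 3 4 5 6", "N C N C C C", "1=2 2-3 3=4 4-5 5=6 6-1"),
    "pyrazine": ("1 2 3 4 5 6", "N C C N C C", "1=2 2-3 3=4 4-5 5=6 6-1"),
    "pyrrole": ("1 2 3 4 5", "N C C C C", "1-2 2=3 3-4 4=5 5-1"),
    "pyrazole": ("1 2 3 4 5", "N N C C C", "1-2 2=3 3-4 4=5 5-1"),
    "imidazole": ("1 2 3 4 5", "N C N C C", "1-2 2=3 3-4 4=5 5-1"),
    "1,2,4-triazole": ("1 2 3 4 5", "N N C N C", "1-2 2=3 3-4 4=5 5-1"),
    "furan": ("1 2 3 4 5", "O C C C C", "1-2 2=3 3-4 4=5 5-1"),
    "thiophene": ("1 2 3 4 5", "S C C C C", "1-2 2=3 3-4 4=5 5-1"),
    "pyrrolidine": ("1 2 3 4 5", "N C C C C", "1-2 2-3 3-4 4-5 5-1"),
    "azetidine": ("1 2 3 4", "N C C C", "1-2 2-3 3-4 4-1"),
    "piperidine": ("1 2 3 4 5 6", "N C C C C C", "1-2 2-3 3-4 4-5 5-6 6-1"),
    "piperazine": ("1 2 3 4 5 6", "N C C N C C", "1-2 2-3 3-4 4-5 5-6 6-1"),
    "morpholine": ("1 2 3 4 5 6", "O C C N C C", "1-2 2-3 3-4 4-5 5-6 6-1"),
    "naphthalene": (
        "1 2 3 4 4a 5 6 7 8 8a", "C C C C C C C C C C",
        "1=2 2-3 3=4 4-4a 4a=8a 8a-1 4a-5 5=6 6-7 7=8 8-8a",
    ),
    "quinoline": (
        "1 2 3 4 4a 5 6 7 8 8a", "N C C C C C C C C C",
        "1=2 2-3 3=4 4-4a 4a=8a 8a-1 4a-5 5=6 6-7 7=8 8-8a",
    ),
    "1,3-benzothiazole": (
        "1 2 3 3a 4 5 6 7 7a", "S C N C C C C C C",
        "1-2 2=3 3-3a 3a=7a 7a-1 3a-4 4=5 5-6 6=7 7-7a",
    ),
    "purine": (
        "1 2 3 4 5 6 7 8 9", "N C N C C C N C N",
        "1=2 2-3 3=4 4-5 5=6 6-1 5-7 7-8 8=9 9-4",
    ),
    "pyrrolizine": (  # 1H-pyrrolizine numbering: N4 and C7a are bridgeheads
        "1 2 3 4 5 6 7 7a", "C C C N C C C C",
        "1-2 2=3 3-4 4-7a 7a=1 4-5 5=6 6-7 7-7a",
    ),
    "imidazo[4,5-b]pyridine": (
        "1 2 3 3a 4 5 6 7 7a", "N C N C N C C C C",
        "1=2 2-3 3-3a 3a=7a 7a-1 3a-4 4=5 5-6 6=7 7-7a",
    ),
    "pyrido[2,3-c]pyridazine": (
        "1 2 3 4 4a 5 6 7 8 8a", "N N C C C C C C N C",
        "1=8a 2=3 1-2 3-4 4=4a 4a-8a 4a-5 5=6 6-7 7=8 8-8a",
    ),
    "pyrido[4,3-d]pyrimidine": (
        "1 2 3 4 4a 5 6 7 8 8a", "N C N C C C N C C C",
        "1=2 2-3 3=4 4-4a 4a=8a 8a-1 4a-5 5=6 6-7 7=8 8-8a",
    ),
}

# Aliases: common elided/implicit-locant spellings of lexicon names.
_RING_ALIASES = {
    "benzothiazole": "1,3-benzothiazole",
    "triazole": "1,2,4-triazole",
}
_RING_NAMES = {**{k: k for k in _RING_SPECS}, **_RING_ALIASES}
_RING_LEXICON_BY_LEN = sorted(_RING_NAMES, key=len, reverse=True)


def _match_ring_lexicon(p: "_Parser") -> Fragment | None:
    """Longest match of a retained ring-system name (with optional elided
    final 'e') at the current position."""
    for name in _RING_LEXICON_BY_LEN:
        stripped = name[:-1] if name.endswith("e") else name
        for cand in (name, stripped):
            if p.s.startswith(cand, p.pos):
                p.pos += len(cand)
                return _lexicon_ring(_RING_NAMES[name])
    return None

# Elided forms: a ring name may drop its final "e" before a vowel suffix
# ("pyridin-2-yl", "purin-9-yl").


def _lexicon_ring(base: str) -> Fragment:
    return _ring_from_spec(*_RING_SPECS[base])


# Simple substituent groups: name -> builder.
def _simple(smiles_atoms: list[tuple[str, int]], bonds: list[tuple[int, int, int]],
            attach: int = 0) -> Fragment:
    frag = Fragment()
    for el, charge in smiles_atoms:
        frag.add_atom(el, charge)
    for i, j, o in bonds:
        frag.add_bond(i, j, o)
    frag.attach = attach
    return frag


def _make_simple_groups() -> dict[str, callable]:
    g: dict[str, callable] = {}
    g["amino"] = lambda: _simple([("N", 0)], [])
    g["hydroxy"] = lambda: _simple([("O", 0)], [])
    g["sulfanyl"] = lambda: _simple([("S", 0)], [])
    g["fluoro"] = lambda: _simple([("F", 0)], [])
    g["chloro"] = lambda: _simple([("Cl", 0)], [])
    g["bromo"] = lambda: _simple([("Br", 0)], [])
    g["iodo"] = lambda: _simple([("I", 0)], [])
    g["cyano"] = lambda: _simple([("C", 0), ("N", 0)], [(0, 1, 3)])
    g["nitro"] = lambda: _simple(
        [("N", 1), ("O", 0), ("O", -1)], [(0, 1, 2), (0, 2, 1)]
    )
    g["carbamoyl"] = lambda: _simple(
        [("C", 0), ("O", 0), ("N", 0)], [(0, 1, 2), (0, 2, 1)]
    )
    g["carboxy"] = lambda: _simple(
        [("C", 0), ("O", 0), ("O", 0)], [(0, 1, 2), (0, 2, 1)]
    )
    g["acetyl"] = lambda: _simple(
        [("C", 0), ("O", 0), ("C", 0)], [(0, 1, 2), (0, 2, 1)]
    )
    g["formyl"] = lambda: _simple([("C", 0), ("O", 0)], [(0, 1, 2)])
    g["methanimidoyl"] = lambda: _simple([("C", 0), ("N", 0)], [(0, 1, 2)])
    g["ethynyl"] = lambda: _simple([("C", 0), ("C", 0)], [(0, 1, 3)])
    g["ethenyl"] = lambda: _simple([("C", 0), ("C", 0)], [(0, 1, 2)])
    # methoxy/ethoxy/... are parsed compositionally (stem + "oxy") so their
    # chain locants stay addressable ("2-aminoethoxy").
    g["tert-butyl"] = lambda: _simple(
        [("C", 0), ("C", 0), ("C", 0), ("C", 0)],
        [(0, 1, 1), (0, 2, 1), (0, 3, 1)],
    )

    def phenyl() -> Fragment:
        frag = _lexicon_ring("benzene")
        frag.attach = frag.locants["1"]
        return frag

    g["phenyl"] = phenyl

    def benzyl() -> Fragment:
        frag = _lexicon_ring("benzene")
        c = frag.add_atom("C")
        frag.add_bond(c, frag.locants["1"], 1)
        frag.attach = c
        return frag

    g["benzyl"] = benzyl
    return g


SIMPLE_GROUPS = _make_simple_groups()
_SIMPLE_BY_LEN = sorted(SIMPLE_GROUPS, key=len, reverse=True)

# Double-bonded substituent prefixes.
DOUBLE_GROUPS = {
    "oxo": "O",
    "sulfanylidene": "S",
    "imino": "N",
    "methylidene": "C",
}

# Connector morphemes chaining substituent units:  R-oxy => R-O-,  etc.
CONNECTORS = {"oxy": "O", "amino": "N", "sulfanyl": "S"}


# ---------------------------------------------------------------------------
# Locant utilities
# ---------------------------------------------------------------------------

_LOCANT_RE = re.compile(
    r"(?P<loc>\d+[a-z]?|N'*)"          # 2, 14, 4a, N, N'
    r"(?:λ(?P<lam>\d))?"               # lambda convention: 3λ5
    r"(?:\((?P<to>\d+[a-z]?)\))?"      # compound ene locant: 1(16)
    r"(?P<ih>H)?"                      # indicated hydrogen run-in: 5H
)

_STEREO_ITEM = re.compile(
    r"\s*(\d+[a-z]?|N'*)?\s*([RSrsEZ])\s*\*?\s*$"
)


@dataclass
class Locant:
    label: str
    lam: int | None = None
    to: str | None = None  # second atom of a compound double-bond locant
    indicated_h: bool = False


def _is_stereo_block(text: str) -> list[tuple[str | None, str]] | None:
    """If *text* is a comma-separated stereodescriptor list, return it."""
    items = text.split(",")
    out = []
    for item in items:
        m = _STEREO_ITEM.match(item)
        if not m:
            return None
        out.append((m.group(1), m.group(2)))
    return out


_CLOSER = {"[": "]", "(": ")"}


def _matching_bracket(s: str, i: int) -> int:
    """Index of the bracket matching s[i]; raises on imbalance."""
    depth = 0
    for j in range(i, len(s)):
        if s[j] in "([":
            depth += 1
        elif s[j] in ")]":
            depth -= 1
            if depth == 0:
                return j
    raise NameParseError(f"unbalanced bracket in {s!r}")


# ---------------------------------------------------------------------------
# The parser
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.s = text
        self.pos = 0

    # -- scanning helpers ---------------------------------------------------

    def rest(self) -> str:
        return self.s[self.pos:]

    def eat(self, literal: str) -> bool:
        if self.s.startswith(literal, self.pos):
            self.pos += len(literal)
            return True
        return False

    def skip_hyphen(self) -> None:
        while self.pos < len(self.s) and self.s[self.pos] == "-":
            self.pos += 1

    def read_locants(self) -> list[Locant] | None:
        """Try to read "2,4,8-"-style locant list (must end before a hyphen
        or a letter that starts a morpheme)."""
        save = self.pos
        locs: list[Locant] = []
        while True:
            m = _LOCANT_RE.match(self.s, self.pos)
            if not m or not m.group("loc"):
                self.pos = save
                return None
            locs.append(
                Locant(
                    m.group("loc"),
                    int(m.group("lam")) if m.group("lam") else None,
                    m.group("to"),
                    bool(m.group("ih")),
                )
            )
            self.pos = m.end()
            if self.eat(","):
                continue
            break
        if self.pos < len(self.s) and self.s[self.pos] == "-":
            self.pos += 1
            return locs
        self.pos = save
        return None

    def read_multiplier(self, include_kis: bool = True) -> int | None:
        if include_kis:
            for name, n in sorted(KIS_MULTIPLIERS.items(), key=lambda kv: -len(kv[0])):
                if self.s.startswith(name, self.pos):
                    self.pos += len(name)
                    return n
        for name in _MULT_BY_LEN:
            if self.s.startswith(name, self.pos):
                # guard: don't eat an alkane stem ("dec" in "decane" is
                # handled by trying stems first at the call sites)
                self.pos += len(name)
                return MULTIPLIERS[name]
        return None

    # -- stereodescriptors --------------------------------------------------

    def maybe_stereo_prefix(self) -> list[str]:
        """Consume a leading "(1R,5S)-" block; returns referenced locants."""
        if self.pos >= len(self.s) or self.s[self.pos] != "(":
            return []
        end = _matching_bracket(self.s, self.pos)
        block = _is_stereo_block(self.s[self.pos + 1 : end])
        if block is None:
            return []
        self.pos = end + 1
        self.skip_hyphen()
        out = []
        for loc, desc in block:
            if desc in ("r", "s"):
                raise StereoError(
                    "pseudo-asymmetric (lowercase r/s) stereodescriptors "
                    "are not supported"
                )
            if desc in ("R", "S") and loc is not None:
                out.append(loc)
        return out


# ---------------------------------------------------------------------------
# Parent construction
# ---------------------------------------------------------------------------


def _read_alkane_stem(p: _Parser) -> int | None:
    for stem in _STEMS_BY_LEN:
        if p.s.startswith(stem, p.pos):
            # avoid eating e.g. "but" of "butyl" prematurely? -- the caller
            # handles what follows; stems are matched longest-first so
            # "tridec" beats "tri"+"dec" ambiguity.
            p.pos += len(stem)
            return ALKANE_STEMS[stem]
    return None


def _parse_von_baeyer(p: _Parser) -> Fragment | None:
    for prefix, n_rings in VON_BAEYER_PREFIXES.items():
        if p.s.startswith(prefix, p.pos):
            p.pos += len(prefix)
            break
    else:
        return None
    if not p.eat("["):
        raise NameParseError("expected '[' after polycyclic prefix")
    end = _matching_bracket(p.s, p.pos - 1)
    descriptor = p.s[p.pos : end]
    p.pos = end + 1
    n_atoms = _read_alkane_stem(p)
    if n_atoms is None:
        raise NameParseError(f"expected alkane stem after [{descriptor}]")
    return _build_von_baeyer(descriptor, n_atoms, n_rings)


def _build_von_baeyer(descriptor: str, n_atoms: int, n_rings: int) -> Fragment:
    parts = descriptor.split(".")
    if len(parts) < 3:
        raise NameParseError(f"von Baeyer descriptor too short: {descriptor}")
    try:
        a, b, c = int(parts[0]), int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise NameParseError(f"bad von Baeyer descriptor: {descriptor}") from exc
    sec_tokens = parts[3:]
    if len(sec_tokens) != n_rings - 2:
        raise NameParseError(
            f"descriptor {descriptor} has {len(sec_tokens)} secondary bridges; "
            f"expected {n_rings - 2}"
        )
    need = n_atoms - (a + b + c + 2)
    # Each flattened token "fx,y" is ambiguous (f and x are concatenated);
    # resolve with the constraint that bridge sizes sum to the atom count.
    candidates: list[list[tuple[int, int, int]]] = [[]]
    for tok in sec_tokens:
        if "," not in tok:
            raise NameParseError(f"bad secondary bridge token {tok!r}")
        left, right = tok.split(",", 1)
        y = int(right)
        opts = []
        for k in range(1, len(left)):
            f, x = int(left[:k]), int(left[k:])
            opts.append((f, x, y))
        if len(left) == 1:  # single digit: bridge size with implicit split
            raise NameParseError(f"bad secondary bridge token {tok!r}")
        new = []
        for cand in candidates:
            for opt in opts:
                new.append(cand + [opt])
        candidates = new
    chosen = None
    for cand in candidates:
        if sum(f for f, _, _ in cand) == need and all(
            1 <= x <= n_atoms and 1 <= y <= n_atoms for _, x, y in cand
        ):
            chosen = cand
            break
    if chosen is None:
        if need < 0 or not sec_tokens:
            raise LocantError(
                f"ring size descriptor [{descriptor}] inconsistent with "
                f"{n_atoms}-atom stem"
            )
        raise LocantError(
            f"could not resolve secondary bridges in [{descriptor}] "
            f"for a {n_atoms}-atom system"
        )

    frag = _chain(n_atoms)  # linear numbering 1..n; now wire the bridges
    frag.bonds = {}
    frag.ring_bonds = set()
    idx = frag.locants

    def bond(x: int, y: int) -> None:
        frag.add_bond(idx[str(x)], idx[str(y)], 1, ring=True)

    b1, b2 = 1, a + 2
    # main bridge a: atoms 2..a+1
    seq = [b1] + list(range(2, a + 2)) + [b2]
    for u, v in zip(seq, seq[1:]):
        bond(u, v)
    # bridge b: atoms a+3..a+b+2 from B2 back to B1
    seq = [b2] + list(range(a + 3, a + b + 3)) + [b1]
    for u, v in zip(seq, seq[1:]):
        bond(u, v)
    # main secondary bridge c: atoms a+b+3..a+b+c+2, numbered from nearer B1
    if c > 0:
        seq = [b1] + list(range(a + b + 3, a + b + c + 3)) + [b2]
        for u, v in zip(seq, seq[1:]):
            bond(u, v)
    else:
        bond(b1, b2)
    nxt = a + b + c + 3
    for f, x, y in chosen:
        hi, lo = max(x, y), min(x, y)
        if f == 0:
            bond(x, y)
        else:
            seq = [hi] + list(range(nxt, nxt + f)) + [lo]
            for u, v in zip(seq, seq[1:]):
                bond(u, v)
            nxt += f
    return frag


def _apply_replacements(frag: Fragment, repls: list[tuple[Locant, str]]) -> None:
    for loc, element in repls:
        idx = frag.resolve(loc.label)
        frag.atoms[idx].element = element
        if loc.lam is not None:
            frag.atoms[idx].lam = loc.lam


def _apply_unsaturation(frag: Fragment, locs: list[Locant], count: int,
                        order: int) -> None:
    """Apply -ene/-yne bonds; compound locants "1(16)" name both ends."""
    if locs and len(locs) != count:
        raise NameParseError("unsaturation locants do not match multiplier")
    if not locs:
        if count != 1:
            raise NameParseError("multiple unsaturations need locants")
        locs = [Locant("1")]
    for loc in locs:
        i = frag.resolve(loc.label)
        if loc.to is not None:
            j = frag.resolve(loc.to)
        else:
            m = re.match(r"\d+", loc.label)
            nxt = str(int(m.group()) + 1) if m else None
            if nxt is None or nxt not in frag.locants:
                raise LocantError(
                    f"cannot place a multiple bond at locant {loc.label}"
                )
            j = frag.locants[nxt]
        frag.set_order(i, j, order)
        frag.broken_sp2.discard(i)
        frag.broken_sp2.discard(j)


# ---------------------------------------------------------------------------
# Segment parsing (prefixes + parent + suffixes)
# ---------------------------------------------------------------------------


@dataclass
class _PrefixUnit:
    locants: list[Locant]
    count: int
    fragment_builder: object  # callable -> Fragment
    double: bool = False
    hydro: bool = False


_SEMANTIC = ("locant", "valency", "stereo", "double-bonds", "suffix",
             "disconnected")


def _wrap_with(element: str, core: Fragment) -> Fragment:
    """New fragment: *element* atom bonded to the core's attachment point.

    The wrapper becomes the attachment point; the core's locants survive so
    that outer locants can still address its skeleton (e.g. ``2-[...]ethoxy``).
    """
    g = Fragment()
    g.add_atom(element)
    off = g.merge(core)
    g.add_bond(0, core.attach + off, 1)
    g.locants = {lab: idx + off for lab, idx in core.locants.items()}
    g.attach = 0
    return g


def _copy_fragment(f: Fragment) -> Fragment:
    g = Fragment()
    g.atoms = [_Atom(a.element, a.charge, a.lam) for a in f.atoms]
    g.bonds = dict(f.bonds)
    g.locants = dict(f.locants)
    g.attach = f.attach
    g.ring_bonds = set(f.ring_bonds)
    g.broken_sp2 = set(f.broken_sp2)
    g.no_double = set(f.no_double)
    return g


def _parse_segment(text: str, as_substituent: bool) -> Fragment:
    """Parse one connected name segment into a Fragment."""
    p = _Parser(text)
    stereo: list[str] = list(p.maybe_stereo_prefix())
    prefixes: list[_PrefixUnit] = []
    parent: Fragment | None = None
    stashed: list[NameParseError] = []

    def try_parent(pend, indicated=None):
        mark = p.pos
        try:
            return _try_parent(p, pend, indicated, as_substituent)
        except NameParseError as exc:
            p.pos = mark
            if exc.category in _SEMANTIC:
                stashed.append(exc)
                return None
            raise

    while parent is None:
        if p.pos >= len(p.s):
            # promote a trailing locant-free prefix unit to the core
            if (as_substituent and prefixes
                    and not prefixes[-1].locants
                    and prefixes[-1].count == 1
                    and not prefixes[-1].hydro
                    and not prefixes[-1].double):
                unit = prefixes.pop()
                parent = unit.fragment_builder()
                break
            if stashed:
                raise stashed[-1]
            raise NameParseError(f"no parent hydride found in {text!r}")
        p.skip_hyphen()
        result = try_parent([])
        if result is not None:
            parent = result
            break
        save = p.pos
        locs = p.read_locants() or []
        if locs and all(l.indicated_h for l in locs):
            result = try_parent([], indicated=locs)
            if result is not None:
                parent = result
                break
            p.pos = save
            locs = []
        elif locs:
            result = try_parent(locs)
            if result is not None:
                parent = result
                break
        try:
            prefixes.append(_parse_prefix_unit(p, locs))
        except NameParseError:
            if stashed:
                raise stashed[-1]
            raise

    frag = parent

    for unit in prefixes:
        if unit.hydro:
            labels = [l.label for l in unit.locants]
            if not labels or len(labels) != unit.count:
                raise UnsupportedNameError(
                    "hydro prefixes need one locant per added hydrogen"
                )
            for lab in labels:
                idx = frag.resolve(lab)
                frag.strip_double(idx)
                frag.no_double.add(idx)
            continue
        if unit.locants:
            if len(unit.locants) != unit.count:
                raise NameParseError(
                    f"{len(unit.locants)} locants for {unit.count} groups "
                    f"in {text!r}"
                )
            sites: list[int | None] = [
                frag.resolve(l.label) for l in unit.locants
            ]
        else:
            sites = [None] * unit.count
        for site in sites:
            sub = unit.fragment_builder()
            if unit.double:
                target = site if site is not None else frag.default_attach_atom()
                frag.strip_double(target)
                frag.no_double.discard(target)
                frag.broken_sp2.discard(target)
                off = frag.merge(sub)
                frag.add_bond(target, sub.attach + off, 2)
            else:
                frag.attach_substituent(sub, site)

    frag.stereo_locants.extend(stereo)
    frag.validate_stereo()

    if p.pos < len(p.s):
        raise NameParseError(
            f"unparsed trailing text {p.s[p.pos:]!r} in {text!r}"
        )
    if as_substituent and frag.attach is None:
        raise NameParseError(f"{text!r} does not name a substituent group")
    return frag


def _parse_prefix_unit(p: _Parser, locs: list[Locant]) -> _PrefixUnit:
    if p.pos < len(p.s) and p.s[p.pos] in "([":
        end = _matching_bracket(p.s, p.pos)
        inner = p.s[p.pos + 1 : end]
        p.pos = end + 1
        frag = _parse_segment(inner, as_substituent=True)
        unit = _PrefixUnit(locs, 1, lambda f=frag: _copy_fragment(f))
        return _maybe_connectors(p, unit, after_bracket=True)
    save = p.pos
    # A direct group match wins over a multiplier reading so that e.g.
    # "pentadecan-8-yl" is a C15 alkyl, not five "decan-8-yl" groups.
    sub = _try_simple_or_alkyl(p, allow_compose=not locs)
    if sub is not None:
        unit = _PrefixUnit(locs, 1, sub[0], double=sub[1])
        return _maybe_connectors(p, unit)
    mult = p.read_multiplier()
    if mult is not None:
        if p.pos < len(p.s) and p.s[p.pos] in "([":
            end = _matching_bracket(p.s, p.pos)
            inner = p.s[p.pos + 1 : end]
            p.pos = end + 1
            frag = _parse_segment(inner, as_substituent=True)
            unit = _PrefixUnit(locs, mult, lambda f=frag: _copy_fragment(f))
            return _maybe_connectors(p, unit)
        sub = _try_simple_or_alkyl(p, allow_compose=False)
        if sub is not None:
            unit = _PrefixUnit(locs, mult, sub[0], double=sub[1])
            return _maybe_connectors(p, unit)
        if p.eat("hydro"):
            return _PrefixUnit(locs, mult, None, hydro=True)
        p.pos = save
    if p.eat("hydro"):
        return _PrefixUnit(locs, 1, None, hydro=True)
    raise NameParseError(f"unrecognised prefix at ...{p.rest()[:40]!r}")


def _maybe_connectors(p: _Parser, unit: _PrefixUnit,
                      after_bracket: bool = False) -> _PrefixUnit:
    """Chain "...yloxy" / "...ylamino" / "...ylsulfanyl" connectors.

    Only single groups chain this way; after a multiplied group
    ("bis(...)amino") the trailing morpheme is the core the copies attach
    to, which the segment loop resolves by promotion.  The same applies to
    a segment-final morpheme after a bracketed group: in "ethyl(methyl)amino"
    the amino is the core, while mid-segment ("[X]oxymethyl") it connects.
    """
    if unit.count != 1 or unit.double:
        return unit
    while True:
        for name, element in CONNECTORS.items():
            if after_bracket and p.pos + len(name) == len(p.s) \
                    and p.s.startswith(name, p.pos):
                return unit
            if p.s.startswith(name, p.pos):
                p.pos += len(name)
                inner = unit.fragment_builder

                def build(b=inner, el=element):
                    return _wrap_with(el, b())

                unit = _PrefixUnit(unit.locants, unit.count, build,
                                   double=unit.double)
                break
        else:
            return unit


def _try_simple_or_alkyl(p: _Parser, allow_compose: bool = True):
    """A simple named group or a compositional alkyl/acyl substituent.

    Returns ``(builder, is_double)`` or None.  When *allow_compose* is true a
    locant-free simple group directly followed by an alkyl core is composed
    into one unit ("carboxymethyl" = HOOC-CH2-).
    """
    for name in sorted(DOUBLE_GROUPS, key=len, reverse=True):
        if p.s.startswith(name, p.pos):
            p.pos += len(name)
            el = DOUBLE_GROUPS[name]
            return (lambda e=el: _simple([(e, 0)], []), True)
    for name in _SIMPLE_BY_LEN:
        if p.s.startswith(name, p.pos):
            p.pos += len(name)
            if allow_compose:
                save = p.pos
                core = _try_alkyl(p)
                if core is not None:
                    def build(n=name, c=core):
                        g = _copy_fragment(c)
                        g.attach_substituent(SIMPLE_GROUPS[n](), g.attach)
                        return g
                    return (build, False)
                p.pos = save
            return (lambda n=name: SIMPLE_GROUPS[n](), False)
    frag = _try_alkyl(p)
    if frag is not None:
        return (lambda f=frag: _copy_fragment(f), False)
    return None


def _acylate(frag: Fragment, label: str) -> Fragment:
    c1 = frag.resolve(label) if label in frag.locants else 0
    o = frag.add_atom("O")
    frag.add_bond(c1, o, 2)
    frag.attach = c1
    return frag


def _try_alkyl(p: _Parser) -> Fragment | None:
    """Alkyl/acyl/alkoxy substituent cores: methyl, pentadecan-8-yl,
    pent-3-ynyl, hex-5-enoyl, ethoxy, cyclohexyl, quinolin-8-yl, ..."""
    save = p.pos
    frag = _match_ring_lexicon(p)
    if frag is None:
        cyclo = p.eat("cyclo")
        vb = None
        if not cyclo:
            try:
                vb = _parse_von_baeyer(p)
            except NameParseError:
                p.pos = save
                return None
        if vb is not None:
            frag = vb
        else:
            n = _read_alkane_stem(p)
            if n is None:
                p.pos = save
                return None
            frag = _chain(n)
            if cyclo:
                if n < 3:
                    p.pos = save
                    return None
                frag.add_bond(frag.locants["1"], frag.locants[str(n)], 1,
                              ring=True)
    while True:
        if p.eat("yl"):
            if frag.attach is None:
                frag.attach = frag.locants.get("1", 0)
            return frag
        if p.eat("oyl"):
            return _acylate(frag, "1")
        if p.eat("oxy"):
            if frag.attach is None:
                frag.attach = frag.locants.get("1", 0)
            return _wrap_with("O", frag)
        save2 = p.pos
        if p.eat("an"):
            p.skip_hyphen()
            locs2 = p.read_locants() or []
            lab = locs2[0].label if locs2 else "1"
            if p.eat("yl"):
                frag.attach = frag.resolve(lab)
                return frag
            if p.eat("oyl"):
                return _acylate(frag, lab)
            if p.eat("oxy"):
                frag.attach = frag.resolve(lab)
                return _wrap_with("O", frag)
            p.pos = save
            return None
        p.skip_hyphen()
        locs = p.read_locants() or []
        if locs and p.eat("yl"):
            frag.attach = frag.resolve(locs[0].label)
            return frag
        if locs and p.eat("oyl"):
            return _acylate(frag, locs[0].label)
        if locs and p.eat("oxy"):
            frag.attach = frag.resolve(locs[0].label)
            return _wrap_with("O", frag)
        mult = p.read_multiplier(include_kis=False) if locs else None
        kind = None
        if p.eat("en"):
            kind = 2
        elif p.eat("yn"):
            kind = 3
        if kind is None:
            if p.eat("a") and p.pos < len(p.s) and p.s[p.pos] == "-":
                continue
            p.pos = save
            return None
        try:
            _apply_unsaturation(frag, locs, mult or 1, kind)
        except NameParseError:
            p.pos = save
            return None


def _parse_substituent_text(text: str) -> Fragment:
    return _parse_segment(text, as_substituent=True)


# ---------------------------------------------------------------------------
# Parent + suffix parsing
# ---------------------------------------------------------------------------

_SUFFIXES = (
    "carboxylic acid", "carboxamide", "carbonitrile", "carbaldehyde",
    "carboxylate", "carbonyl",
    "amine", "imine", "ol", "one", "al", "thiol", "nitrile", "oic acid",
    "oate", "amide", "yl",
)
_SUFFIXES_BY_LEN = sorted(_SUFFIXES, key=len, reverse=True)


def _try_parent(p: _Parser, locs_pending: list[Locant],
                indicated: list[Locant] | None, as_substituent: bool):
    save = p.pos
    result = _parse_parent_inner(p, locs_pending, indicated or [])
    if result is None:
        p.pos = save
    return result


def _parse_parent_inner(p: _Parser, locs_pending: list[Locant],
                        indicated: list[Locant]):
    # special parents ------------------------------------------------------
    if p.s.startswith("azanium", p.pos) and p.pos + 7 == len(p.s):
        p.pos += 7
        frag = Fragment()
        frag.add_atom("N", charge=1, locant="1")
        return frag
    if p.s.startswith("cyanamide", p.pos) and p.pos + 9 == len(p.s):
        p.pos += 9
        frag = Fragment()
        n1 = frag.add_atom("N", locant="1")
        c = frag.add_atom("C", locant="2")
        n2 = frag.add_atom("N", locant="N")
        frag.add_bond(n1, c, 3)
        frag.add_bond(c, n2, 1)
        return frag
    if p.s.startswith("aniline", p.pos) and p.pos + 7 == len(p.s):
        p.pos += 7
        frag = _lexicon_ring("benzene")
        n = frag.add_atom("N", locant="N")
        frag.add_bond(frag.locants["1"], n, 1)
        return frag

    # skeletal replacement prefixes ----------------------------------------
    repls: list[tuple[Locant, str]] = []
    pend = list(locs_pending)
    while True:
        save = p.pos
        matched = False
        mult = 1
        m = p.read_multiplier(include_kis=False)
        if m is not None:
            mult = m
        for rname, el in REPLACEMENT_ELEMENTS.items():
            if p.s.startswith(rname, p.pos):
                if len(pend) != mult:
                    p.pos = save
                    return None
                p.pos += len(rname)
                repls.extend((l, el) for l in pend)
                pend = []
                matched = True
                break
        if not matched:
            if m is not None:
                p.pos = save
            break
        p.skip_hyphen()
        nxt = p.read_locants()
        pend = nxt if nxt else []

    # the ring/chain hydride ------------------------------------------------
    frag = _match_ring_lexicon(p)
    ring_lexicon = frag is not None
    chain_like = False
    if frag is None:
        cyclo = p.eat("cyclo")
        vb = None
        if not cyclo:
            vb = _parse_von_baeyer(p)
        if vb is not None:
            frag = vb
            chain_like = True
        else:
            n = _read_alkane_stem(p)
            if n is None:
                return None
            frag = _chain(n)
            chain_like = True
            if cyclo:
                if n < 3:
                    return None
                frag.add_bond(frag.locants["1"], frag.locants[str(n)], 1,
                              ring=True)
    if repls:
        _apply_replacements(frag, repls)

    for loc in indicated:
        idx = frag.resolve(loc.label)
        frag.strip_double(idx)
        frag.no_double.add(idx)

    if chain_like:
        ok = _parse_hydride_tail(p, frag)
        if not ok:
            return None

    if not _parse_suffixes(p, frag, pend):
        return None
    if p.pos != len(p.s):
        return None
    return frag


def _parse_hydride_tail(p: _Parser, frag: Fragment) -> bool:
    """Consume "ane"/"an"/"a-1,3-dien"-style hydride tails after a stem."""
    if p.eat("ane"):
        return True
    if p.s.startswith("an", p.pos) and not p.s.startswith("ani", p.pos):
        p.pos += 2
        return True
    saw = False
    while True:
        save = p.pos
        p.eat("a")
        p.skip_hyphen()
        locs = p.read_locants() or []
        mult = p.read_multiplier(include_kis=False) if locs else None
        kind = None
        if p.eat("en"):
            kind = 2
        elif p.eat("yn"):
            kind = 3
        if kind is None:
            p.pos = save
            break
        _apply_unsaturation(frag, locs, mult or 1, kind)
        p.eat("e")
        saw = True
    if saw:
        return True
    # elided hydride tail before yl/oyl/oxy ("propyl", "hexanoyl" handled
    # above; "propyl" reaches here with the tail fully elided)
    return p.s.startswith(("yl", "oyl", "oxy"), p.pos)


def _add_carboxyl(frag: Fragment, site: int, kind: str) -> None:
    c = frag.add_atom("C")
    o = frag.add_atom("O")
    frag.add_bond(c, o, 2)
    frag.add_bond(site, c, 1)
    if kind == "acid":
        oh = frag.add_atom("O")
        frag.add_bond(c, oh, 1)
    elif kind == "ester":
        oe = frag.add_atom("O")
        frag.add_bond(c, oe, 1)
        frag.attach = oe  # the ester oxygen bonds the alcohol-derived group
    elif kind == "amide":
        n = frag.add_atom("N")
        frag.add_bond(c, n, 1)
        base = "N"
        while base in frag.locants:
            base += "'"
        frag.locants[base] = n


def _parse_suffixes(p: _Parser, frag: Fragment, pend: list[Locant]) -> bool:
    """Parse the suffix chain after the hydride tail; mutates *frag*."""
    while p.pos < len(p.s):
        p.skip_hyphen()
        locs = p.read_locants() or []
        if not locs and pend:
            locs, pend = pend, []
        p.skip_hyphen()
        mult = p.read_multiplier(include_kis=False)
        if p.eat("en"):
            try:
                _apply_unsaturation(frag, locs, mult or 1, 2)
            except NameParseError:
                return False
            p.eat("e")
            continue
        if p.eat("yn"):
            try:
                _apply_unsaturation(frag, locs, mult or 1, 3)
            except NameParseError:
                return False
            p.eat("e")
            continue
        matched = None
        for suffix in _SUFFIXES_BY_LEN:
            if p.s.startswith(suffix, p.pos):
                matched = suffix
                p.pos += len(suffix)
                break
        if matched is None:
            return bool(p.eat("e") and p.pos == len(p.s))
        count = mult or 1
        if locs and len(locs) != count and matched != "yl":
            return False
        sites = [frag.resolve(l.label) for l in locs] if locs \
            else [None] * count
        for site in sites:
            if site is None:
                idx = frag.locants.get("1", 0) if matched in (
                    "yl", "oic acid", "oate", "al", "amide", "nitrile"
                ) else frag.default_attach_atom()
            else:
                idx = site
            if matched == "yl":
                frag.attach = idx
            elif matched == "ol":
                frag.add_bond(idx, frag.add_atom("O"), 1)
            elif matched == "thiol":
                frag.add_bond(idx, frag.add_atom("S"), 1)
            elif matched == "one":
                frag.strip_double(idx)
                frag.add_bond(idx, frag.add_atom("O"), 2)
            elif matched in ("al", "carbaldehyde"):
                if matched == "carbaldehyde":
                    c = frag.add_atom("C")
                    frag.add_bond(idx, c, 1)
                    idx = c
                frag.add_bond(idx, frag.add_atom("O"), 2)
            elif matched in ("amine", "imine"):
                n = frag.add_atom("N")
                frag.add_bond(idx, n, 2 if matched == "imine" else 1)
                base = "N"
                while base in frag.locants:
                    base += "'"
                frag.locants[base] = n
            elif matched == "carboxylic acid":
                _add_carboxyl(frag, idx, "acid")
            elif matched == "carboxylate":
                _add_carboxyl(frag, idx, "ester")
            elif matched == "carboxamide":
                _add_carboxyl(frag, idx, "amide")
            elif matched == "carbonitrile":
                c = frag.add_atom("C")
                n = frag.add_atom("N")
                frag.add_bond(idx, c, 1)
                frag.add_bond(c, n, 3)
            elif matched == "oic acid":
                # the existing C1 is the acid carbon
                frag.add_bond(idx, frag.add_atom("O"), 2)
                frag.add_bond(idx, frag.add_atom("O"), 1)
            elif matched == "oate":
                frag.add_bond(idx, frag.add_atom("O"), 2)
                oe = frag.add_atom("O")
                frag.add_bond(idx, oe, 1)
                frag.attach = oe
            elif matched == "amide":
                frag.add_bond(idx, frag.add_atom("O"), 2)
                n = frag.add_atom("N")
                frag.add_bond(idx, n, 1)
                base = "N"
                while base in frag.locants:
                    base += "'"
                frag.locants[base] = n
            elif matched == "nitrile":
                frag.add_bond(idx, frag.add_atom("N"), 3)
            elif matched == "carbonyl":
                c = frag.add_atom("C")
                frag.add_bond(idx, c, 1)
                frag.add_bond(c, frag.add_atom("O"), 2)
                frag.attach = c
            else:
                raise SuffixError(
                    f"suffix {matched!r} cannot be applied to this group"
                )
    return True


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

# Lexicon names carrying their own locant descriptors are normalised before
# parsing so that the descriptors are not mistaken for substituent locants.
_NAME_NORMALISATIONS = (
    ("1,3-benzothiazol", "benzothiazol"),
    ("1,2,4-triazol", "triazol"),
    # multiplier+aza contractions ("pentaza" = penta + aza)
    ("tetraza", "tetraaza"),
    ("pentaza", "pentaaza"),
    ("hexaza", "hexaaza"),
    ("heptaza", "heptaaza"),
    ("octaza", "octaaza"),
)


def parse_name(name: str) -> Chem.Mol:
    """Parse an IUPAC name into an RDKit molecule.

    Raises a :class:`NameParseError` subclass describing the failure
    category when the name is malformed, inconsistent with itself, or
    outside the supported grammar.
    """
    original = name
    name = name.strip()
    if not name:
        raise NameParseError("empty name")
    if ";" in name:
        raise DisconnectedNameError(
            "IUPAC names for disconnected molecules cannot be parsed",
            original,
        )
    if "spiro" in name:
        raise UnsupportedNameError(
            "spiro ring-fusion nomenclature is not supported", original
        )
    for old, new in _NAME_NORMALISATIONS:
        name = name.replace(old, new)
    try:
        return _parse_name_inner(name)
    except NameParseError as exc:
        exc.name = original
        raise


def _parse_name_inner(name: str) -> Chem.Mol:
    words = _split_words(name)
    if len(words) == 1:
        frag = _parse_segment(words[0], as_substituent=False)
        if frag.attach is not None:
            raise NameParseError(f"{name!r} names a group, not a molecule")
        return frag.to_mol()
    if len(words) == 2 and words[1] == "hypofluorite":
        sub = _parse_segment(words[0], as_substituent=True)
        frag = Fragment()
        o = frag.add_atom("O")
        f = frag.add_atom("F")
        frag.add_bond(o, f, 1)
        off = frag.merge(sub)
        frag.add_bond(o, sub.attach + off, 1)
        return frag.to_mol()
    if len(words) == 2:
        acid = _parse_segment(words[1], as_substituent=False)
        if acid.attach is None:
            raise SuffixError(f"expected an ester suffix in {words[1]!r}")
        alcohol = _parse_segment(words[0], as_substituent=True)
        ester_o = acid.attach
        off = acid.merge(alcohol)
        acid.add_bond(ester_o, alcohol.attach + off, 1)
        acid.attach = None
        return acid.to_mol()
    raise UnsupportedNameError(
        f"cannot interpret a name with {len(words)} words"
    )


def _split_words(name: str) -> list[str]:
    """Split on bracket-depth-zero spaces, re-joining two-word suffixes."""
    words: list[str] = []
    depth = 0
    cur: list[str] = []
    for ch in name:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        if ch == " " and depth == 0:
            words.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    words.append("".join(cur))
    merged: list[str] = []
    for w in words:
        if w == "acid" and merged and (
            merged[-1].endswith("carboxylic") or merged[-1].endswith("oic")
        ):
            merged[-1] = merged[-1] + " " + w
        else:
            merged.append(w)
    return [w for w in merged if w]


def name_to_structure(name: str) -> str:
    """Parse *name* and return its canonical kekulised isomeric SMILES."""
    return canonicalize_mol(parse_name(name))
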