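"""Synthetic paired (SMILES, IUPAC name) corpora over a restricted subspace.

Training a name-translation model needs data where every structure carries
exactly one deterministic systematic name.  This module enumerates acyclic
hydrocarbon skeletons (all non-isomorphic carbon trees up to a size limit),
decorates them with a configurable set of simple substituents (hydroxy, oxo,
amino, halogens; methyl/ethyl branching arises from the skeletons
themselves), and names each structure with a deterministic simplified-IUPAC
namer (longest chain, lowest locants, alphabetical prefixes, multiplying
prefixes).

The namer and the name parser (:mod:`chemnmt.nomen`) are independent code
paths; every emitted pair is validated by the round trip
``canonicalize(parse(name)) == smiles`` and silently-discarded otherwise, so
the emitted corpus satisfies the one-name-per-structure contract by
construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from rdkit import Chem

from .corpus import PairRecord, canonicalize_smiles
from .nomen import NameParseError, name_to_structure

_STEM = {1: "methan", 2: "ethan", 3: "propan", 4: "butan", 5: "pentan",
         6: "hexan", 7: "heptan", 8: "octan", 9: "nonan", 10: "decan",
         11: "undecan", 12: "dodecan"}
_MULT = {2: "di", 3: "tri", 4: "tetra"}

# substituent name -> (attached fragment, principal-suffix name or None)
_DECORATIONS = {
    "methyl": ("C", None),
    "ethyl": ("CC", None),
    "hydroxy": ("O", "ol"),
    "oxo": ("=O", "one"),
    "amino": ("N", "amine"),
    "fluoro": ("F", None),
    "chloro": ("Cl", None),
    "bromo": ("Br", None),
}
# suffix seniority (higher wins the suffix slot; the rest become prefixes)
_SENIORITY = ["one", "ol", "amine"]


@dataclass
class SubspaceConfig:
    """The chemical subspace the generator covers.

    ``max_carbons`` bounds the skeleton size; ``substituents`` is drawn from
    hydroxy / oxo / amino / fluoro / chloro / bromo (methyl and ethyl
    branches come from skeleton enumeration); ``max_substituents`` caps the
    decorations per structure.
    """

    max_carbons: int = 8
    substituents: tuple[str, ...] = ("hydroxy",)
    max_substituents: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_carbons < 1:
            raise ValueError("max_carbons must be >= 1")
        for s in self.substituents:
            if s not in _DECORATIONS and s not in ("methyl", "ethyl"):
                raise ValueError(f"unsupported substituent {s!r}")


# ---------------------------------------------------------------------------
# Skeleton enumeration: all non-isomorphic carbon trees (degree <= 4)
# ---------------------------------------------------------------------------


def _tree_smiles(adj: dict[int, list[int]]) -> str:
    def walk(node: int, parent: int | None) -> str:
        parts = []
        for nb in adj[node]:
            if nb != parent:
                parts.append(f"({walk(nb, node)})")
        return "C" + "".join(parts)

    return canonicalize_smiles(walk(0, None))


def enumerate_skeletons(max_carbons: int) -> list[str]:
    """Canonical SMILES of every acyclic alkane with 1..max_carbons atoms."""
    levels: list[set[str]] = [set(), {"C"}]
    out = ["C"]
    current: list[dict[int, list[int]]] = [{0: []}]
    for n in range(2, max_carbons + 1):
        seen: set[str] = set()
        nxt: list[dict[int, list[int]]] = []
        for adj in current:
            for node in list(adj):
                if len(adj[node]) >= 4:
                    continue
                new = {k: list(v) for k, v in adj.items()}
                idx = len(new)
                new[idx] = [node]
                new[node] = new[node] + [idx]
                smi = _tree_smiles(new)
                if smi not in seen:
                    seen.add(smi)
                    nxt.append(new)
        current = nxt
        out.extend(sorted(seen))
        levels.append(seen)
    return out


def enumerate_structures(cfg: SubspaceConfig) -> list[str]:
    """Deduplicated canonical SMILES of the configured subspace."""
    skeletons = enumerate_skeletons(cfg.max_carbons)
    decorations = [s for s in cfg.substituents if s in _DECORATIONS]
    results: set[str] = set(skeletons)
    for skel in skeletons:
        mol = Chem.MolFromSmiles(skel)
        n = mol.GetNumAtoms()
        sites: list[tuple[int, str]] = []
        for idx in range(n):
            atom = mol.GetAtomWithIdx(idx)
            degree = atom.GetDegree()
            for dec in decorations:
                if dec == "oxo":
                    # ketones only: oxo on carbons with 2+ carbon neighbours
                    if degree >= 2 and degree <= 2:
                        sites.append((idx, dec))
                elif degree < 4:
                    sites.append((idx, dec))
        for k in range(1, cfg.max_substituents + 1):
            for combo in itertools.combinations(sites, k):
                smi = _decorate(skel, combo)
                if smi is not None:
                    results.add(smi)
    return sorted(results)


def _decorate(skeleton: str, combo) -> str | None:
    mol = Chem.RWMol(Chem.MolFromSmiles(skeleton))
    for idx, dec in combo:
        frag, _ = _DECORATIONS[dec]
        double = frag.startswith("=")
        symbols = frag.lstrip("=")
        prev = idx
        for pos, symbol in enumerate(symbols):
            new = mol.AddAtom(Chem.Atom(symbol))
            btype = Chem.BondType.DOUBLE if double and pos == 0 \
                else Chem.BondType.SINGLE
            mol.AddBond(prev, new, btype)
            prev = new
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
    except Exception:
        return None
    return canonicalize_smiles(Chem.MolToSmiles(m))


# ---------------------------------------------------------------------------
# Deterministic simplified-IUPAC namer
# ---------------------------------------------------------------------------


class UnsupportedStructureError(ValueError):
    pass


def name_structure(smiles: str) -> str:
    """One deterministic systematic name for a structure in the subspace.

    Longest-chain selection (suffix groups first, then length, then most
    substituents), lowest-locant numbering, alphabetical prefix ordering and
    di/tri/tetra multiplying prefixes.  Raises
    :class:`UnsupportedStructureError` outside the acyclic subspace.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnsupportedStructureError(f"unparseable SMILES {smiles!r}")
    if mol.GetRingInfo().NumRings() > 0:
        raise UnsupportedStructureError("rings are outside the subspace")

    carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    groups: dict[int, list[str]] = {}  # carbon idx -> decoration names
    nitrile_like = False
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "C":
            continue
        nbrs = atom.GetNeighbors()
        if len(nbrs) != 1 or nbrs[0].GetSymbol() != "C":
            raise UnsupportedStructureError(
                f"unsupported heteroatom environment for {sym}"
            )
        ci = nbrs[0].GetIdx()
        bond = mol.GetBondBetweenAtoms(atom.GetIdx(), ci)
        if sym == "O":
            dec = "oxo" if bond.GetBondTypeAsDouble() == 2 else "hydroxy"
        elif sym == "N":
            if bond.GetBondTypeAsDouble() != 1:
                raise UnsupportedStructureError("multiple C-N bonds")
            dec = "amino"
        elif sym == "F":
            dec = "fluoro"
        elif sym == "Cl":
            dec = "chloro"
        elif sym == "Br":
            dec = "bromo"
        else:
            raise UnsupportedStructureError(f"element {sym} not supported")
        groups.setdefault(ci, []).append(dec)

    # carbon adjacency
    adj: dict[int, list[int]] = {c: [] for c in carbons}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetSymbol() == "C" and b.GetSymbol() == "C":
            if bond.GetBondTypeAsDouble() != 1:
                raise UnsupportedStructureError("C=C bonds not supported")
            adj[a.GetIdx()].append(b.GetIdx())
            adj[b.GetIdx()].append(a.GetIdx())

    suffix = next(
        (s for s in _SENIORITY
         if any(_DECORATIONS[d][1] == s for decs in groups.values()
                for d in decs)),
        None,
    )

    chains = _candidate_chains(adj)
    best = None
    for chain in chains:
        for path in (chain, chain[::-1]):
            key = _chain_key(path, adj, groups, suffix)
            if best is None or key < best[0]:
                best = (key, path)
    chain = best[1]
    return _assemble_name(chain, adj, groups, suffix)


def _candidate_chains(adj: dict[int, list[int]]) -> list[list[int]]:
    nodes = sorted(adj)
    if len(nodes) == 1:
        return [[nodes[0]]]
    leaves = [n for n in nodes if len(adj[n]) == 1]
    paths = []
    for a, b in itertools.combinations(leaves, 2):
        # unique path in a tree via DFS
        stack = [(a, [a])]
        while stack:
            node, path = stack.pop()
            if node == b:
                paths.append(path)
                break
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))
    return paths


def _chain_key(path, adj, groups, suffix):
    on_chain = set(path)
    suffix_locs = tuple(
        i + 1 for i, c in enumerate(path)
        if any(_DECORATIONS[d][1] == suffix for d in groups.get(c, []))
    ) if suffix else ()
    n_suffix_on_chain = len(suffix_locs)
    prefix_locs = []
    for i, c in enumerate(path):
        for d in groups.get(c, []):
            if not suffix or _DECORATIONS[d][1] != suffix:
                prefix_locs.append(i + 1)
        for nb in adj[c]:
            if nb not in on_chain:
                prefix_locs.append(i + 1)
    # more suffix groups on chain, longer chain, more substituents,
    # then lowest suffix locants, then lowest substituent locants
    return (
        -n_suffix_on_chain,
        -len(path),
        -len(prefix_locs),
        suffix_locs,
        tuple(sorted(prefix_locs)),
    )


def _branch_name(root: int, parent: int, adj, groups) -> str:
    """Name the subtree hanging off the main chain as a substituent."""
    # collect subtree nodes
    sub = []
    stack = [root]
    seen = {parent}
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        sub.append(node)
        stack.extend(adj[node])
    # longest path within subtree starting at root
    best_path = [root]
    stack = [(root, [root])]
    while stack:
        node, path = stack.pop()
        if len(path) > len(best_path):
            best_path = path
        for nb in adj[node]:
            if nb in seen and nb not in path and nb != parent and nb in sub:
                stack.append((nb, path + [nb]))
    length = len(best_path)
    on_path = set(best_path)
    inner: list[tuple[int, str]] = []
    for i, c in enumerate(best_path):
        for d in groups.get(c, []):
            inner.append((i + 1, d))
        for nb in adj[c]:
            if nb in sub and nb not in on_path and nb != parent:
                if any(m in sub and m not in on_path and m != c
                       for m in adj[nb]):
                    raise UnsupportedStructureError("doubly nested branch")
                inner.append((i + 1, "methyl"))
    stem = {1: "meth", 2: "eth", 3: "prop", 4: "but", 5: "pent",
            6: "hex"}.get(length)
    if stem is None:
        raise UnsupportedStructureError("branch too long to name")
    if not inner:
        return f"{stem}yl"
    # only single-decoration branches occur in this subspace
    if len(inner) == 1:
        loc, d = inner[0]
        return f"{loc}-{d}{stem}yl"
    raise UnsupportedStructureError("multiply substituted branch")


def _assemble_name(chain, adj, groups, suffix) -> str:
    on_chain = set(chain)
    suffix_locs = []
    prefixes: dict[str, list[int]] = {}
    for i, c in enumerate(chain):
        loc = i + 1
        for d in groups.get(c, []):
            if suffix and _DECORATIONS[d][1] == suffix:
                suffix_locs.append(loc)
            else:
                prefixes.setdefault(d, []).append(loc)
        for nb in adj[c]:
            if nb not in on_chain:
                bname = _branch_name(nb, c, adj, groups)
                prefixes.setdefault(bname, []).append(loc)

    def sort_key(name: str) -> str:
        # alphabetise ignoring any leading locant of composite branches
        return name.lstrip("0123456789-")

    parts = []
    for name in sorted(prefixes, key=sort_key):
        locs = sorted(prefixes[name])
        locstr = ",".join(str(l) for l in locs)
        if len(locs) == 1:
            if any(ch.isdigit() for ch in name):  # composite: bracket it
                parts.append(f"{locstr}-({name})")
            else:
                parts.append(f"{locstr}-{name}")
        else:
            mult = _MULT.get(len(locs))
            if mult is None:
                raise UnsupportedStructureError("too many identical groups")
            if any(ch.isdigit() for ch in name):
                kis = {2: "bis", 3: "tris", 4: "tetrakis"}[len(locs)]
                parts.append(f"{locstr}-{kis}({name})")
            else:
                parts.append(f"{locstr}-{mult}{name}")
    prefix_str = "-".join(parts)
    stem = _STEM.get(len(chain))
    if stem is None:
        raise UnsupportedStructureError("chain too long to name")
    if suffix is None:
        base = stem + "e"
    else:
        locs = sorted(suffix_locs)
        locstr = ",".join(str(l) for l in locs)
        if len(locs) == 1:
            base = f"{stem}-{locstr}-{suffix}"
        else:
            mult = _MULT.get(len(locs))
            if mult is None:
                raise UnsupportedStructureError("too many suffix groups")
            base = f"{stem}e-{locstr}-{mult}{suffix}"
    if prefix_str:
        return prefix_str + base
    return base


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


@dataclass
class GenerationLog:
    emitted: int = 0
    discarded: list[tuple[str, str, str]] = field(default_factory=list)


def generate_corpus(cfg: SubspaceConfig, n: int | None = None
                    ) -> tuple[list[PairRecord], GenerationLog]:
    """Generate validated (SMILES, name) pairs for the configured subspace.

    Every emitted pair satisfies ``canonicalize(parse(name)) == smiles``;
    pairs failing the check are discarded and logged.  Output order is
    deterministic for a given config; ``n`` subsamples deterministically
    from the seeded shuffle.
    """
    import numpy as np

    structures = enumerate_structures(cfg)
    log = GenerationLog()
    records: list[PairRecord] = []
    for smi in structures:
        try:
            name = name_structure(smi)
        except UnsupportedStructureError as exc:
            log.discarded.append((smi, "", f"namer: {exc}"))
            continue
        try:
            back = name_to_structure(name)
        except NameParseError as exc:
            log.discarded.append((smi, name, f"parser: {exc}"))
            continue
        if back != smi:
            log.discarded.append((smi, name, f"round trip gave {back}"))
            continue
        records.append(PairRecord(smi, name, source_tag="synthetic"))
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    if n is not None:
        records = records[:n]
    log.emitted = len(records)
    return records, log
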