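"""MaxMin diverse-subset selection for train/test construction.

The greedy MaxMin picker starts from a chosen item and repeatedly adds the
item whose minimum distance to everything already selected is largest, which
spreads the selection across the occupied chemical space.  The implementation
here is the exact O(k*n) incremental greedy (ties broken by lowest index);
an external picker is used only as a cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


@dataclass
class FingerprintSet:
    """Fixed-width binary fingerprints with parallel record identifiers."""

    bitvectors: np.ndarray  # (n, width) uint8 0/1
    ids: list[str]

    def __post_init__(self) -> None:
        self.bitvectors = np.asarray(self.bitvectors, dtype=np.uint8)
        if self.bitvectors.ndim != 2:
            raise ValueError("bitvectors must be a 2-D array")
        if len(self.ids) != self.bitvectors.shape[0]:
            raise ValueError("ids must parallel bitvectors")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    @property
    def width(self) -> int:
        return self.bitvectors.shape[1]

    def __len__(self) -> int:
        return self.bitvectors.shape[0]


def morgan_fingerprints(smiles: Sequence[str], radius: int = 2,
                        n_bits: int = 2048) -> FingerprintSet:
    """Hashed circular (Morgan) fingerprints, the default selection features."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return FingerprintSet(rows, list(smiles))


def _distances_to(fps: np.ndarray, idx: int, metric: str) -> np.ndarray:
    """Distance from item *idx* to every item, for the supported metrics."""
    if metric == "absolute":  # 1-D numeric stand-ins, used by oracle tests
        return np.abs(fps[:, 0].astype(np.float64) - float(fps[idx, 0]))
    a = fps[idx].astype(np.int64)
    if metric == "hamming":
        return np.abs(fps.astype(np.int64) - a).sum(axis=1).astype(np.float64)
    if metric == "tanimoto":
        inter = (fps & fps[idx]).sum(axis=1).astype(np.float64)
        union = (fps | fps[idx]).sum(axis=1).astype(np.float64)
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        return 1.0 - sim
    raise ValueError(f"unknown distance metric {metric!r}")


def maxmin_select(fps: FingerprintSet | np.ndarray, k: int,
                  start_index: int = 0, distance: str = "tanimoto") -> list[int]:
    """Greedy MaxMin selection of *k* indices.

    Begins at *start_index*; each subsequent pick maximises the minimum
    distance to all already-selected items, ties broken by lowest index.
    Returns the indices in pick order.
    """
    vectors = fps.bitvectors if isinstance(fps, FingerprintSet) else np.asarray(fps)
    if vectors.ndim == 1:
        vectors = vectors[:, None]
    n = vectors.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if not 0 <= start_index < n:
        raise ValueError(f"start_index={start_index} out of range")
    selected = [start_index]
    min_dist = _distances_to(vectors, start_index, distance)
    min_dist[start_index] = -np.inf
    for _ in range(k - 1):
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, _distances_to(vectors, nxt, distance))
        min_dist[nxt] = -np.inf
    return selected


def maxmin_split(smiles: Sequence[str], n_test: int, seed: int = 0,
                 distance: str = "tanimoto") -> tuple[list[int], list[int]]:
    """Disjoint (train, test) index lists; the test set is MaxMin-diverse.

    The test subset is picked greedily from the full fingerprint set starting
    at a seed-chosen item; everything else becomes training material.
    """
    fps = morgan_fingerprints(smiles)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(fps)))
    test_idx = maxmin_select(fps, n_test, start_index=start, distance=distance)
    test_set = set(test_idx)
    train_idx = [i for i in range(len(fps)) if i not in test_set]
    return train_idx, test_idx
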