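import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemnmt.diversity import (FingerprintSet, maxmin_select, maxmin_split,
                               morgan_fingerprints)


def brute_force_maxmin(dist, k, start):
    """Exhaustive greedy oracle over a precomputed distance matrix."""
    n = dist.shape[0]
    selected = [start]
    while len(selected) < k:
        best_idx, best_min = None, -1.0
        for cand in range(n):
            if cand in selected:
                continue
            d = min(dist[cand, s] for s in selected)
            if d > best_min:
                best_min, best_idx = d, cand
        selected.append(best_idx)
    return selected


class TestMaxMin:
    def test_one_dimensional_hand_case(self):
        """Points {0,1,2,10}: from 0 the picks are 0 -> 10 -> 2."""
        points = np.array([[0], [1], [2], [10]])
        picks = maxmin_select(points, k=3, start_index=0, distance="absolute")
        assert picks == [0, 3, 2]
        assert [int(points[i, 0]) for i in picks] == [0, 10, 2]

    def test_k_equals_n_returns_everything(self):
        points = np.array([[0], [5], [9]])
        for start in range(3):
            picks = maxmin_select(points, k=3, start_index=start,
                                  distance="absolute")
            assert sorted(picks) == [0, 1, 2]

    def test_duplicates_deferred(self):
        points = np.array([[0], [0], [7], [3]])
        picks = maxmin_select(points, k=3, start_index=0, distance="absolute")
        assert 1 not in picks  # the duplicate of the start is never chosen

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            maxmin_select(np.zeros((3, 4)), k=4)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10 ** 6), st.integers(2, 30), st.data())
    def test_agrees_with_brute_force_oracle(self, seed, n, data):
        rng = np.random.default_rng(seed)
        fps = (rng.random((n, 16)) < 0.4).astype(np.uint8)
        k = data.draw(st.integers(1, n))
        start = data.draw(st.integers(0, n - 1))
        inter = fps @ fps.T
        pop = fps.sum(axis=1)
        union = pop[:, None] + pop[None, :] - inter
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        assert maxmin_select(fps, k, start, "tanimoto") == \
            brute_force_maxmin(dist, k, start)

    def test_hamming_metric(self):
        fps = np.array([[0, 0, 0], [1, 1, 1], [1, 0, 0]], dtype=np.uint8)
        assert maxmin_select(fps, 2, 0, "hamming") == [0, 1]

    def test_independent_picker_cross_check(self):
        """Agreement with the RDKit MaxMin picker on a tie-free instance."""
        from rdkit import DataStructs
        from rdkit.SimDivFilters.rdSimDivPickers import MaxMinPicker

        rng = np.random.default_rng(42)
        n, width = 25, 64
        fps = (rng.random((n, width)) < 0.35).astype(np.uint8)
        bvs = []
        for row in fps:
            bv = DataStructs.ExplicitBitVect(width)
            for j in np.flatnonzero(row):
                bv.SetBit(int(j))
            bvs.append(bv)

        def dist(i, j, bvs=bvs):
            return 1.0 - DataStructs.TanimotoSimilarity(bvs[i], bvs[j])

        picker = MaxMinPicker()
        ours = maxmin_select(fps, 10, start_index=0, distance="tanimoto")
        theirs = list(picker.LazyPick(dist, n, 10, firstPicks=[0]))
        assert ours == theirs


class TestFingerprintSet:
    def test_invariants(self):
        with pytest.raises(ValueError, match="unique"):
            FingerprintSet(np.zeros((2, 8), dtype=np.uint8), ["a", "a"])
        with pytest.raises(ValueError):
            FingerprintSet(np.zeros(8, dtype=np.uint8), ["a"])

    def test_morgan_width_and_ids(self):
        fps = morgan_fingerprints(["CCO", "CCC"], n_bits=512)
        assert fps.width == 512 and len(fps) == 2
        with pytest.raises(ValueError):
            morgan_fingerprints(["C("])


class TestMaxMinSplit:
    def test_disjoint_and_complete(self):
        smiles = [f"{'C' * (i + 1)}O" for i in range(12)]
        train, test = maxmin_split(smiles, n_test=4, seed=1)
        assert not set(train) & set(test)
        assert sorted(train + test) == list(range(12))

    def test_seeded_determinism(self):
        smiles = [f"{'C' * (i + 1)}O" for i in range(12)]
        assert maxmin_split(smiles, 4, seed=9) == maxmin_split(smiles, 4, seed=9)
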