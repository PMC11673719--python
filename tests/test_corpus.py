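import pytest
from hypothesis import given, settings, strategies as st

from chemnmt.corpus import (CanonicalizationError, PairRecord,
                            canonicalize_smiles, compute_stats, deduplicate,
                            filter_by_length, read_pairs, read_shards,
                            write_pairs, write_shards)
from chemnmt.tokens import tokenize_iupac_chars, tokenize_smiles


class TestCanonicalize:
    @pytest.mark.parametrize("raw,canonical", [
        ("OCC", "CCO"),
        ("CCO", "CCO"),
        ("c1ccccc1", "C1=CC=CC=C1"),  # kekulised output
        ("C(C)(C)C", "CC(C)C"),
    ])
    def test_known_forms(self, raw, canonical):
        assert canonicalize_smiles(raw) == canonical

    @pytest.mark.parametrize("raw", ["OCC", "c1ccc2ccccc2c1", "N[C@@H](C)C(=O)O",
                                     "F/C=C/F", "CC(=O)Oc1ccccc1C(=O)O"])
    def test_idempotent(self, raw):
        once = canonicalize_smiles(raw)
        assert canonicalize_smiles(once) == once

    def test_stereo_preserved(self):
        assert "@" in canonicalize_smiles("N[C@@H](C)C(=O)O")

    @pytest.mark.parametrize("bad", ["C(", "xyz", "C1CC"])
    def test_rejects_unparseable(self, bad):
        with pytest.raises(CanonicalizationError, match="unparseable"):
            canonicalize_smiles(bad)


class TestPairRecord:
    def test_rejects_embedded_tabs(self):
        with pytest.raises(ValueError):
            PairRecord("CCO", "etha\tnol")

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            PairRecord("", "ethanol")


class TestFilterByLength:
    def test_boundary_is_inclusive(self):
        records = [PairRecord("C" * n, "x") for n in (599, 600, 601)]
        kept = filter_by_length(records, max_smiles=600, max_name=100)
        assert [len(r.smiles) for r in kept] == [599, 600]

    def test_order_preserved(self):
        records = [PairRecord(f"{'C' * (i + 1)}", f"name{i}") for i in range(10)]
        assert filter_by_length(records, 600, 700) == records

    def test_empty(self):
        assert filter_by_length([], 10, 10) == []


class TestDeduplicate:
    def test_first_wins_and_conflicts_reported(self):
        records = [PairRecord("CCO", "ethanol"),
                   PairRecord("CCO", "ethyl alcohol"),
                   PairRecord("CCO", "ethanol"),
                   PairRecord("CC", "ethane")]
        kept, conflicts = deduplicate(records)
        assert [r.name for r in kept] == ["ethanol", "ethane"]
        assert conflicts == {"CCO": ["ethanol", "ethyl alcohol"]}

    def test_idempotent_and_never_grows(self):
        records = [PairRecord("C" * (i % 3 + 1), str(i)) for i in range(9)]
        once, _ = deduplicate(records)
        twice, conflicts = deduplicate(once)
        assert twice == once and not conflicts
        assert len(once) <= len(records)


records_strategy = st.lists(
    st.builds(
        PairRecord,
        st.text(alphabet="CNOFc1()=[]@+-", min_size=1, max_size=40),
        st.text(alphabet="abcdefgh 0123456789,-", min_size=1, max_size=60)
        .filter(lambda s: s.strip()),
        st.sampled_from(["", "synthetic", "test"]),
    ),
    max_size=25,
)


class TestShards:
    def test_single_shard_when_budget_large(self, tmp_path):
        records = [PairRecord("CCO", f"name{i}") for i in range(10)]
        manifest = write_shards(records, 10 ** 6, tmp_path)
        assert len(manifest["shards"]) == 1
        assert manifest["shards"][0]["records"] == 10

    @settings(max_examples=25, deadline=None)
    @given(records=records_strategy, budget=st.integers(8, 200))
    def test_round_trip_identity(self, records, budget, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("shards")
        write_shards(records, budget, tmp)
        assert list(read_shards(tmp)) == records

    def test_multi_shard_concatenation(self, tmp_path):
        records = [PairRecord("C" * 30, f"n{i}", "t") for i in range(20)]
        manifest = write_shards(records, 100, tmp_path)
        assert len(manifest["shards"]) > 1
        assert list(read_shards(tmp_path)) == records

    def test_gzip_round_trip(self, tmp_path):
        records = [PairRecord("CCO", "ethanol")] * 5
        write_shards(records, 50, tmp_path, compress=True)
        assert list(read_shards(tmp_path)) == records

    def test_manifest_records_canonicalizer(self, tmp_path):
        manifest = write_shards([PairRecord("C", "methane")], 100, tmp_path,
                                seed=7)
        assert manifest["canonicalizer"].startswith("rdkit-")
        assert manifest["seed"] == 7


def test_pair_tsv_round_trip(tmp_path):
    records = [PairRecord("CCO", "ethanol", "synthetic"),
               PairRecord("CC", "ethane")]
    path = tmp_path / "pairs.tsv"
    write_pairs(records, path)
    assert read_pairs(path) == records


def test_compute_stats_counts_tokens():
    records = [PairRecord("CCO", "ethanol"), PairRecord("CCCl", "1-chloropropane")]
    stats = compute_stats(
        records,
        smiles_tokens=lambda s: tokenize_smiles(s).tokens,
        name_tokens=lambda s: tokenize_iupac_chars(s).tokens,
    )
    assert stats.record_count == 2
    assert stats.max_smiles_length == 4
    assert stats.max_name_length == len("1-chloropropane")
    assert stats.unique_smiles_tokens == 3  # C, O, Cl
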