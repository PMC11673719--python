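import json

import pytest
from hypothesis import given, settings, strategies as st

from chemnmt.tokens import (END_ID, PAD_ID, START_ID, UNK_ID, SequenceLengthError,
                            TokenSequence, TokenizationError, Vocabulary,
                            build_vocab, decode, encode, tokenize,
                            tokenize_iupac_chars, tokenize_iupac_words,
                            tokenize_smiles)


class TestSmilesTokenizer:
    @pytest.mark.parametrize("smiles,expected", [
        ("CCO", ["C", "C", "O"]),
        ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
        ("[NH4+]", ["[NH4+]"]),
        ("CCl", ["C", "Cl"]),
        ("BrC=C", ["Br", "C", "=", "C"]),
        ("C1=CC=CC=C1", ["C", "1", "=", "C", "C", "=", "C", "C", "=", "C", "1"]),
        ("N[C@@H](C)C(=O)O",
         ["N", "[C@@H]", "(", "C", ")", "C", "(", "=", "O", ")", "O"]),
    ])
    def test_token_boundaries(self, smiles, expected):
        assert list(tokenize_smiles(smiles).tokens) == expected

    @pytest.mark.parametrize("smiles", [
        "CCO", "C%12CC%12", "[NH4+]", "ClCCBr", "C1=CC=CC=C1",
        "CC(=O)O[C@H]1CC[C@@H](N)C1",
    ])
    def test_lossless(self, smiles):
        assert tokenize_smiles(smiles).text() == smiles

    def test_unbalanced_bracket_raises(self):
        with pytest.raises(TokenizationError, match="bracket"):
            tokenize_smiles("C[NH4")


class TestIupacCharTokenizer:
    def test_one_token_per_character(self):
        seq = tokenize_iupac_chars("2,2-dimethylpropane")
        assert len(seq.tokens) == len("2,2-dimethylpropane") == 19
        assert seq.tokens[0] == "2" and seq.tokens[3] == "-"

    @pytest.mark.parametrize("name", ["ethanol", "2-methylpropan-1-ol",
                                      "N-methylbutanamide", "x y z"])
    def test_identity(self, name):
        seq = tokenize_iupac_chars(name)
        assert seq.text() == name
        assert len(seq.tokens) == len(name)


class TestIupacWordTokenizer:
    def test_morpheme_split(self):
        assert list(tokenize_iupac_words("2-methylpropane").tokens) == \
            ["2", "-", "methyl", "propane"]

    def test_suffix_split(self):
        assert list(tokenize_iupac_words("ethanol").tokens) == ["ethan", "ol"]

    @pytest.mark.parametrize("name", [
        "2,2-dimethylpropan-1-ol", "5-bromo-2-methylheptan-3-one",
        "weirdunknownword-42", "bis[ethyl(methyl)amino]azanium",
    ])
    def test_lossless_on_arbitrary_names(self, name):
        assert tokenize_iupac_words(name).text() == name


class TestVocabulary:
    def test_specials_layout(self):
        vocab = build_vocab([tokenize_smiles("CCO")])
        assert vocab.token(PAD_ID) == "<pad>"
        assert vocab.token(START_ID) == "<start>"
        assert vocab.token(END_ID) == "<end>"
        assert vocab.token(UNK_ID) == "<unk>"
        assert len(vocab) == 2 + 4  # C, O + specials

    def test_deterministic_across_order(self):
        seqs = [tokenize_smiles(s) for s in ["CCO", "CCN", "ClC"]]
        v1 = build_vocab(seqs)
        v2 = build_vocab(list(reversed(seqs)))
        assert v1.id_to_token == v2.id_to_token

    def test_save_load_stable(self, tmp_path):
        vocab = build_vocab([tokenize_iupac_chars("ethanol")])
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        vocab.save(p1)
        Vocabulary.load(p1).save(p2)
        assert p1.read_text() == p2.read_text()


class TestEncodeDecode:
    def test_layout(self):
        vocab = build_vocab([tokenize_smiles("CCO")])
        ids = encode(tokenize_smiles("CCO"), vocab, max_len=6)
        c, o = vocab.id("C"), vocab.id("O")
        assert ids == [START_ID, c, c, o, END_ID, PAD_ID]

    def test_no_pad_at_exact_length(self):
        vocab = build_vocab([tokenize_smiles("CCO")])
        ids = encode(tokenize_smiles("CCO"), vocab, max_len=5)
        assert ids[-1] == END_ID

    def test_overlength_raises(self):
        vocab = build_vocab([tokenize_smiles("CCO")])
        with pytest.raises(SequenceLengthError):
            encode(tokenize_smiles("CCCCCC"), vocab, max_len=5)

    def test_unknown_maps_to_unk(self):
        vocab = build_vocab([tokenize_smiles("CCO")])
        with pytest.warns(UserWarning, match="not in vocabulary"):
            ids = encode(tokenize_smiles("CCN"), vocab, max_len=8)
        assert UNK_ID in ids
        assert "<unk>" in decode(ids, vocab)

    def test_degenerate_decodes(self):
        vocab = build_vocab([tokenize_smiles("CCO")])
        assert decode([PAD_ID] * 4, vocab) == ""
        assert decode([START_ID, END_ID], vocab) == ""

    def test_out_of_range_id_raises(self):
        vocab = build_vocab([tokenize_smiles("CCO")])
        with pytest.raises(KeyError):
            decode([START_ID, 99, END_ID], vocab)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="CNOPS()=#123", min_size=1, max_size=30))
    def test_round_trip_smiles_mode(self, text):
        seq = tokenize_smiles(text)
        vocab = build_vocab([seq])
        ids = encode(seq, vocab, max_len=len(seq.tokens) + 4)
        assert decode(ids, vocab) == text

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="abcdxyz0123,-[]() ", min_size=1, max_size=40))
    def test_round_trip_char_mode(self, text):
        seq = tokenize_iupac_chars(text)
        vocab = build_vocab([seq])
        ids = encode(seq, vocab, max_len=len(seq.tokens) + 2)
        assert decode(ids, vocab) == text


def test_mode_dispatch():
    assert tokenize("CCO", "smiles").mode == "smiles"
    assert tokenize("ethanol", "iupac_char").mode == "iupac_char"
    assert tokenize("ethanol", "iupac_word").mode == "iupac_word"
    with pytest.raises(ValueError):
        tokenize("x", "bogus")
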