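"""Tokenisers and vocabularies for SMILES strings and IUPAC names.

Three token modes are supported:

``smiles``
    Atom-level splitting: bracket atoms ``[...]`` are single tokens, the
    two-letter organic-subset halogens ``Cl``/``Br`` are single tokens, as are
    ``%nn`` two-digit ring closures, ring digits, bond symbols, branch
    parentheses and stereo markers.
``iupac_char``
    One token per character.  The winning strategy for name generation: a
    small, closed token set at the cost of longer sequences.
``iupac_word``
    Morpheme-level splitting on punctuation, locant runs and a versioned
    lexicon of nomenclature morphemes (multiplying prefixes, parent stems,
    suffixes).  Kept as a comparison baseline.

All three modes are lossless: ``"".join(tokens)`` reproduces the input string
exactly, so the neural model is free to learn over whichever granularity is
configured without any information loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

PAD_ID, START_ID, END_ID, UNK_ID = 0, 1, 2, 3
SPECIALS = ("<pad>", "<start>", "<end>", "<unk>")

Mode = str  # "smiles" | "iupac_char" | "iupac_word"


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]
    mode: Mode

    def text(self) -> str:
        return "".join(self.tokens)


def tokenize_smiles(smiles: str) -> TokenSequence:
    """Atom-level SMILES tokenisation; concatenation of tokens == input."""
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        c = smiles[i]
        if c == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(f"unbalanced bracket in {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif c == "]":
            raise TokenizationError(f"unbalanced bracket in {smiles!r}")
        elif c == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise TokenizationError(f"malformed %nn ring closure in {smiles!r}")
            tokens.append(smiles[i : i + 3])
            i += 3
        elif c in "CB" and i + 1 < n and smiles[i : i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(c)
            i += 1
    return TokenSequence(tuple(tokens), "smiles")


def tokenize_iupac_chars(name: str) -> TokenSequence:
    """One token per character; token count equals string length."""
    if not name:
        raise TokenizationError("empty name")
    return TokenSequence(tuple(name), "iupac_char")


# Morpheme lexicon for word-level splitting (version 1).  Greedy longest-match
# from the left inside each alphabetic chunk; punctuation and digit runs are
# always their own tokens.  Any unmatched character falls back to a
# single-character token, which keeps the split lossless on arbitrary input.
WORD_LEXICON_VERSION = 1
_MULTIPLIERS = (
    "bis", "tris", "tetrakis", "pentakis", "hexakis",
    "di", "tri", "tetra", "penta", "hexa", "hepta", "octa", "nona", "deca",
    "undeca", "dodeca",
)
_PARENT_STEMS = (
    "methan", "ethan", "propan", "butan", "pentan", "hexan", "heptan",
    "octan", "nonan", "decan", "undecan", "dodecan",
    "methane", "ethane", "propane", "butane", "pentane", "hexane", "heptane",
    "octane", "nonane", "decane", "undecane", "dodecane",
    "benzene", "phenyl", "pyridine", "purine", "cyclo",
)
_SUBSTITUENTS = (
    "methyl", "ethyl", "propyl", "butyl", "pentyl", "hexyl", "heptyl",
    "octyl", "fluoro", "chloro", "bromo", "iodo", "hydroxy", "amino",
    "oxo", "methoxy", "ethoxy", "sulfanyl", "oxy",
)
_SUFFIXES = (
    "carboxylic acid", "carboxylate", "carboxamide", "carbonitrile",
    "amine", "imine", "ol", "one", "al", "ane", "ene", "yne", "yl",
    "oic acid", "oate", "ium", "e",
)
_LEXICON = tuple(
    sorted(set(_MULTIPLIERS + _PARENT_STEMS + _SUBSTITUENTS + _SUFFIXES),
           key=len, reverse=True)
)


def _split_alpha_chunk(chunk: str) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(chunk):
        for morpheme in _LEXICON:
            if chunk.startswith(morpheme, i):
                out.append(morpheme)
                i += len(morpheme)
                break
        else:
            out.append(chunk[i])
            i += 1
    return out


def tokenize_iupac_words(name: str) -> TokenSequence:
    """Morpheme-level splitting; ``"".join(tokens)`` reconstructs the name."""
    if not name:
        raise TokenizationError("empty name")
    tokens: list[str] = []
    i, n = 0, len(name)
    while i < n:
        c = name[i]
        if c.isdigit():
            j = i
            while j < n and name[j].isdigit():
                j += 1
            tokens.append(name[i:j])
            i = j
        elif c.isalpha():
            j = i
            while j < n and name[j].isalpha():
                j += 1
            tokens.extend(_split_alpha_chunk(name[i:j]))
            i = j
        else:  # punctuation, brackets, hyphens, commas, spaces, primes
            tokens.append(c)
            i += 1
    return TokenSequence(tuple(tokens), "iupac_word")


def tokenize(text: str, mode: Mode) -> TokenSequence:
    if mode == "smiles":
        return tokenize_smiles(text)
    if mode == "iupac_char":
        return tokenize_iupac_chars(text)
    if mode == "iupac_word":
        return tokenize_iupac_words(text)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------


class Vocabulary:
    """Bidirectional token<->id map with reserved specials.

    Ids are contiguous from 0; the four specials occupy 0..3 and corpus tokens
    are assigned ids in sorted order, which makes vocabulary construction a
    deterministic, order-independent function of the token set.
    """

    def __init__(self, tokens: Iterable[str]):
        corpus_tokens = sorted(set(tokens) - set(SPECIALS))
        self.id_to_token: list[str] = list(SPECIALS) + corpus_tokens
        self.token_to_id: dict[str, int] = {
            t: i for i, t in enumerate(self.id_to_token)
        }

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def token(self, idx: int) -> str:
        if not 0 <= idx < len(self.id_to_token):
            raise KeyError(f"id {idx} not in vocabulary of size {len(self)}")
        return self.id_to_token[idx]

    def save(self, path: str | Path) -> None:
        payload = {
            "specials": {t: i for i, t in enumerate(SPECIALS)},
            "tokens": self.id_to_token[len(SPECIALS):],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, ensure_ascii=False)

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(payload["tokens"])


def build_vocab(sequences: Sequence[TokenSequence]) -> Vocabulary:
    if not sequences:
        raise ValueError("need at least one sequence")
    tokens: set[str] = set()
    for seq in sequences:
        tokens.update(seq.tokens)
    return Vocabulary(tokens)


class SequenceLengthError(ValueError):
    pass


def encode(
    seq: TokenSequence, vocab: Vocabulary, max_len: int, warn_unknown: bool = True
) -> list[int]:
    """``[start] + ids + [end]`` padded with pad-id to exactly *max_len*."""
    if len(seq.tokens) + 2 > max_len:
        raise SequenceLengthError(
            f"sequence of {len(seq.tokens)} tokens exceeds max_len={max_len}: "
            f"{seq.text()[:60]!r}..."
        )
    ids = [START_ID]
    for tok in seq.tokens:
        idx = vocab.id(tok)
        if idx == UNK_ID and tok not in SPECIALS and warn_unknown:
            warnings.warn(f"token {tok!r} not in vocabulary; mapped to <unk>")
        ids.append(idx)
    ids.append(END_ID)
    ids.extend([PAD_ID] * (max_len - len(ids)))
    return ids


def decode(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`encode` on its image: strip specials, join tokens."""
    out: list[str] = []
    for idx in ids:
        idx = int(idx)
        if idx == PAD_ID or idx == START_ID:
            continue
        if idx == END_ID:
            break
        tok = vocab.token(idx)  # raises KeyError on out-of-range ids
        out.append(tok)
    return "".join(out)
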