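"""End-to-end translation: canonicalise, tokenise, decode, detokenise.

A :class:`ModelBundle` couples a trained transformer with the vocabularies and
token modes it was trained on, so translation is a single call in either
direction.  Every SMILES input is canonicalised before tokenisation, which
guarantees that all spellings of one molecule produce byte-identical
predictions.  Decoding is greedy argmax: the toolkit reports a single
deterministic name per structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import canonicalize_smiles
from .model import Transformer
from .tokens import (END_ID, PAD_ID, START_ID, TokenSequence, Vocabulary,
                     encode, tokenize)

# Decode caps: generated names may run to ~1000 characters, SMILES to 600.
MAX_NAME_DECODE = 1000
MAX_SMILES_DECODE = 600


@dataclass
class TranslationResult:
    input_text: str
    predicted_text: str
    decode_steps: int
    truncated: bool


def greedy_decode(model: Transformer, input_ids: np.ndarray,
                  max_decode_len: int) -> tuple[list[int], bool]:
    """Autoregressive argmax decoding.

    Starts from the start-id, repeatedly appends the most probable next token
    and stops at the end-id or after *max_decode_len* generated tokens.
    Returns ``(ids, truncated)`` where *ids* includes the start/end specials.
    Deterministic given model + input.
    """
    inp = np.asarray(input_ids, dtype=np.int64).reshape(1, -1)
    enc_out = model.encode(inp)
    out = [START_ID]
    truncated = True
    for _ in range(max_decode_len):
        dec_in = np.asarray(out, dtype=np.int64).reshape(1, -1)
        logits = model.decode(enc_out, inp, dec_in)
        nxt = int(logits.data[0, -1].argmax())
        out.append(nxt)
        if nxt == END_ID:
            truncated = False
            break
    return out, truncated


class ModelBundle:
    """A trained model plus its vocabularies and token modes."""

    def __init__(self, model: Transformer, vocab_in: Vocabulary,
                 vocab_out: Vocabulary, mode_in: str, mode_out: str):
        self.model = model
        self.vocab_in = vocab_in
        self.vocab_out = vocab_out
        self.mode_in = mode_in
        self.mode_out = mode_out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.model.save(directory / "model")
        self.vocab_in.save(directory / "vocab_in.json")
        self.vocab_out.save(directory / "vocab_out.json")
        with open(directory / "bundle.json", "w", encoding="utf-8") as fh:
            json.dump({"mode_in": self.mode_in, "mode_out": self.mode_out}, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        with open(directory / "bundle.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            Transformer.load(directory / "model"),
            Vocabulary.load(directory / "vocab_in.json"),
            Vocabulary.load(directory / "vocab_out.json"),
            meta["mode_in"],
            meta["mode_out"],
        )

    def _translate(self, text: str, max_decode_len: int) -> TranslationResult:
        seq = tokenize(text, self.mode_in)
        ids = encode(seq, self.vocab_in, len(seq.tokens) + 2, warn_unknown=False)
        out_ids, truncated = greedy_decode(self.model, ids, max_decode_len)
        tokens = []
        for idx in out_ids:
            if idx in (PAD_ID, START_ID):
                continue
            if idx == END_ID:
                break
            tokens.append(self.vocab_out.token(idx))
        return TranslationResult(
            input_text=text,
            predicted_text="".join(tokens),
            decode_steps=len(out_ids) - 1,
            truncated=truncated,
        )


def smiles_to_name(bundle: ModelBundle, smiles: str,
                   max_decode_len: int = MAX_NAME_DECODE) -> TranslationResult:
    """Canonicalise *smiles*, then translate it to an IUPAC name.

    Raises :class:`~chemnmt.corpus.CanonicalizationError` on unparseable input;
    equivalent SMILES spellings of one molecule yield identical predictions.
    """
    canonical = canonicalize_smiles(smiles)
    result = bundle._translate(canonical, max_decode_len)
    result.input_text = smiles
    return result


def name_to_smiles(bundle: ModelBundle, name: str,
                   max_decode_len: int = MAX_SMILES_DECODE) -> TranslationResult:
    """Translate an IUPAC name to a SMILES string (reverse-direction bundle)."""
    return bundle._translate(name, max_decode_len)
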