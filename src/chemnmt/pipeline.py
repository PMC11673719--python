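"""End-to-end wiring: pair records -> vocabularies -> arrays -> trained bundle.

The helpers here are what the command-line interface drives; they are also
the shortest path from a synthetic corpus to a working translation model in
a few lines:

    records, _ = synthetic.generate_corpus(SubspaceConfig(...))
    bundle = pipeline.train_translation_model(records, direction="s2n")
    infer.smiles_to_name(bundle, "CC(C)CO").predicted_text
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import PairRecord
from .infer import ModelBundle
from .model import Adam, ModelConfig, TrainState, Transformer, train
from .tokens import (TokenSequence, Vocabulary, build_vocab, encode, tokenize)


@dataclass
class EncodedPairs:
    inputs: np.ndarray
    targets: np.ndarray
    vocab_in: Vocabulary
    vocab_out: Vocabulary
    mode_in: str
    mode_out: str
    max_input_len: int
    max_target_len: int


def encode_pairs(
    records: Sequence[PairRecord],
    direction: str = "s2n",
    name_mode: str = "iupac_char",
    vocab_in: Vocabulary | None = None,
    vocab_out: Vocabulary | None = None,
    max_input_len: int | None = None,
    max_target_len: int | None = None,
) -> EncodedPairs:
    """Tokenise and encode pair records for one translation direction.

    ``direction`` is ``"s2n"`` (SMILES -> name) or ``"n2s"``.  Vocabularies
    and maximum lengths default to those observed in the records, making the
    encoding a deterministic function of the corpus.
    """
    if direction not in ("s2n", "n2s"):
        raise ValueError("direction must be 's2n' or 'n2s'")
    mode_in, mode_out = ("smiles", name_mode) if direction == "s2n" \
        else (name_mode, "smiles")
    src = [r.smiles if direction == "s2n" else r.name for r in records]
    dst = [r.name if direction == "s2n" else r.smiles for r in records]
    in_seqs = [tokenize(s, mode_in) for s in src]
    out_seqs = [tokenize(s, mode_out) for s in dst]
    vocab_in = vocab_in or build_vocab(in_seqs)
    vocab_out = vocab_out or build_vocab(out_seqs)
    max_input_len = max_input_len or (
        max(len(s.tokens) for s in in_seqs) + 2
    )
    max_target_len = max_target_len or (
        max(len(s.tokens) for s in out_seqs) + 2
    )
    inputs = np.asarray(
        [encode(s, vocab_in, max_input_len, warn_unknown=False)
         for s in in_seqs], dtype=np.int64)
    targets = np.asarray(
        [encode(s, vocab_out, max_target_len, warn_unknown=False)
         for s in out_seqs], dtype=np.int64)
    return EncodedPairs(inputs, targets, vocab_in, vocab_out,
                        mode_in, mode_out, max_input_len, max_target_len)


def train_translation_model(
    records: Sequence[PairRecord],
    direction: str = "s2n",
    config: ModelConfig | None = None,
    epochs: int = 60,
    max_steps: int | None = None,
    seed: int = 0,
    checkpoint_dir=None,
    log_path=None,
) -> tuple[ModelBundle, list[TrainState]]:
    """Train a translation model on *records* and return the bundle."""
    enc = encode_pairs(records, direction)
    if config is None:
        config = ModelConfig.desk_scale(
            input_vocab=len(enc.vocab_in),
            target_vocab=len(enc.vocab_out),
            max_input_len=enc.max_input_len,
            max_target_len=enc.max_target_len,
            seed=seed,
        )
    model = Transformer(config)
    history = train(
        model, (enc.inputs, enc.targets), config,
        epochs=epochs, max_steps=max_steps,
        checkpoint_dir=checkpoint_dir, log_path=log_path,
    )
    bundle = ModelBundle(model, enc.vocab_in, enc.vocab_out,
                         enc.mode_in, enc.mode_out)
    return bundle, history
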