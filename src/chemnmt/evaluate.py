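"""Round-trip evaluation harness for name-translation models.

Implements the full test battery used to judge SMILES -> IUPAC translation:

* exact string match (any deviation, however small, is a miss);
* BLEU-1..4 with the standard brevity penalty;
* retranslation of every predicted name back to a structure with the
  rule-based IUPAC parser, comparison against the reference structure via
  881-bit substructure-key fingerprints and the Tanimoto coefficient;
* the failure-as-zero convention: predictions that do not parse back into a
  valid structure contribute a Tanimoto of 0 to the mean rather than being
  dropped, giving a conservative aggregate;
* length-stratified reporting over fixed 60-character windows of the input
  SMILES (1: 0-60, 2: 61-120, ..., 10: 541-600).
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import canonicalize_smiles
from .fingerprints import N_BITS, fingerprint_smiles
from .nomen import NameParseError, name_to_structure


def exact_match(pred: str, ref: str) -> bool:
    """Byte equality; case or whitespace differences are misses."""
    return pred == ref


# ---------------------------------------------------------------------------
# BLEU
# ---------------------------------------------------------------------------

_BLEU_TOKEN = re.compile(r"[A-Za-z]+|\d+|\S")


def _bleu_tokens(text: str) -> list[str]:
    """Word-level tokens: letter runs, digit runs, punctuation marks.

    BLEU over raw characters saturates for chemical names, so scoring uses
    word-and-punctuation tokens.
    """
    return _BLEU_TOKEN.findall(text)


def _modified_precision(pred: list[str], ref: list[str], n: int) -> float | None:
    pred_ngrams = Counter(tuple(pred[i:i + n]) for i in range(len(pred) - n + 1))
    if not pred_ngrams:
        return None
    ref_ngrams = Counter(tuple(ref[i:i + n]) for i in range(len(ref) - n + 1))
    clipped = sum(min(c, ref_ngrams[g]) for g, c in pred_ngrams.items())
    return clipped / sum(pred_ngrams.values())


def sentence_bleu(pred: str, ref: str, max_n: int = 4) -> float:
    """BLEU-``max_n`` for one sentence: geometric mean of modified n-gram
    precisions times the brevity penalty.  No smoothing: a missing n-gram
    order yields 0."""
    p_tok, r_tok = _bleu_tokens(pred), _bleu_tokens(ref)
    if not p_tok:
        return 0.0
    logs = []
    for n in range(1, max_n + 1):
        p = _modified_precision(p_tok, r_tok, n)
        if p is None or p == 0.0:
            return 0.0
        logs.append(math.log(p))
    bp = 1.0 if len(p_tok) >= len(r_tok) else math.exp(1 - len(r_tok) / len(p_tok))
    return bp * math.exp(sum(logs) / max_n)


def brevity_penalty(pred: str, ref: str) -> float:
    p_tok, r_tok = _bleu_tokens(pred), _bleu_tokens(ref)
    if not p_tok:
        return 0.0
    return 1.0 if len(p_tok) >= len(r_tok) else math.exp(1 - len(r_tok) / len(p_tok))


def bleu_suite(preds: Sequence[str], refs: Sequence[str]) -> dict:
    """Corpus BLEU-1..4 averages, their mean, and the perfect fraction."""
    if len(preds) != len(refs):
        raise ValueError("prediction and reference lists differ in length")
    per_n = {n: [] for n in range(1, 5)}
    perfect = 0
    for pred, ref in zip(preds, refs):
        for n in range(1, 5):
            per_n[n].append(sentence_bleu(pred, ref, max_n=n))
        if per_n[4][-1] == 1.0:
            perfect += 1
    out = {f"bleu{n}": float(np.mean(per_n[n])) if per_n[n] else 0.0
           for n in range(1, 5)}
    out["average"] = float(np.mean([out[f"bleu{n}"] for n in range(1, 5)]))
    out["perfect_fraction"] = perfect / len(preds) if preds else 0.0
    return out


# ---------------------------------------------------------------------------
# Structure retranslation + Tanimoto
# ---------------------------------------------------------------------------


def retranslate(name: str) -> tuple[str | None, str | None]:
    """Parse an IUPAC name back to canonical SMILES.

    Returns ``(smiles, None)`` on success or ``(None, diagnostic)`` on
    failure; the diagnostic is prefixed with the failure category.  The
    parser runs in-process, so parser availability is never in question and
    every failure is a data-level parse failure.
    """
    try:
        return name_to_structure(name), None
    except NameParseError as exc:
        return None, f"{exc.category}: {exc}"


def pubchem_fp(smiles: str) -> np.ndarray:
    """881-bit substructure-key fingerprint for a SMILES string."""
    fp = fingerprint_smiles(smiles)
    assert fp.shape == (N_BITS,)
    return fp


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a & b| / |a | b| over equal-width bit vectors.

    Defined as 1.0 when both vectors are all-zero, so identical (featureless)
    structures compare as identical.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint widths differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def name_pair_tanimoto(reference_name: str, predicted_name: str) -> float:
    """Parse two names and return the Tanimoto of their fingerprints."""
    ref_smiles, ref_err = retranslate(reference_name)
    pred_smiles, pred_err = retranslate(predicted_name)
    if ref_err is not None:
        raise NameParseError(f"reference name failed to parse: {ref_err}")
    if pred_err is not None:
        return 0.0
    return tanimoto(pubchem_fp(ref_smiles), pubchem_fp(pred_smiles))


# ---------------------------------------------------------------------------
# Round-trip evaluation
# ---------------------------------------------------------------------------


@dataclass
class RoundTripOutcome:
    predicted_name: str
    parsed_smiles: str | None
    parse_error: str | None
    tanimoto: float
    identical_name: bool
    identical_structure: bool


@dataclass
class LengthBin:
    bin_index: int
    char_range: tuple[int, int]
    n: int
    exact_match_pct: float | None
    retranslation_pct: float | None
    mean_tanimoto: float | None
    overflow: bool = False


@dataclass
class EvaluationReport:
    n: int
    exact_match_pct: float
    valid_pct: float
    tanimoto_one_pct: float
    mean_tanimoto: float
    bleu: dict
    length_bins: list[LengthBin] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def round_trip_eval(
    reference_names: Sequence[str],
    predicted_names: Sequence[str],
    reference_smiles: Sequence[str] | None = None,
) -> tuple[list[RoundTripOutcome], EvaluationReport]:
    """Evaluate predicted names against references structure-by-structure.

    The reference structure comes from the supplied SMILES column when
    present, otherwise from parsing the reference name.  Failures are data:
    an unparseable prediction scores Tanimoto 0 and counts as invalid.
    """
    if len(reference_names) != len(predicted_names):
        raise ValueError("reference/prediction lists differ in length")
    outcomes: list[RoundTripOutcome] = []
    for i, (ref, pred) in enumerate(zip(reference_names, predicted_names)):
        if reference_smiles is not None and reference_smiles[i]:
            ref_smiles = canonicalize_smiles(reference_smiles[i])
        else:
            ref_smiles, ref_err = retranslate(ref)
            if ref_err is not None:
                outcomes.append(RoundTripOutcome(
                    pred, None, f"reference unparseable ({ref_err})",
                    0.0, exact_match(pred, ref), False))
                continue
        pred_smiles, pred_err = retranslate(pred)
        if pred_err is not None:
            outcomes.append(RoundTripOutcome(
                pred, None, pred_err, 0.0, exact_match(pred, ref), False))
            continue
        t = tanimoto(pubchem_fp(ref_smiles), pubchem_fp(pred_smiles))
        outcomes.append(RoundTripOutcome(
            pred, pred_smiles, None, t, exact_match(pred, ref),
            pred_smiles == ref_smiles))
    report = summarize(outcomes, bleu_suite(predicted_names, reference_names))
    return outcomes, report


def summarize(outcomes: Sequence[RoundTripOutcome], bleu: dict | None = None
              ) -> EvaluationReport:
    """Aggregate a report directly from per-item outcomes."""
    n = len(outcomes)
    if n == 0:
        return EvaluationReport(0, 0.0, 0.0, 0.0, 0.0, bleu or {})
    valid = [o for o in outcomes if o.parse_error is None]
    return EvaluationReport(
        n=n,
        exact_match_pct=100.0 * sum(o.identical_name for o in outcomes) / n,
        valid_pct=100.0 * len(valid) / n,
        tanimoto_one_pct=100.0 * sum(o.tanimoto == 1.0 for o in valid) / n,
        mean_tanimoto=float(np.mean([o.tanimoto for o in outcomes])),
        bleu=bleu or {},
    )


def length_stratified(
    outcomes: Sequence[RoundTripOutcome], input_smiles: Sequence[str]
) -> list[LengthBin]:
    """Bin outcomes by input-SMILES length into fixed 60-character windows.

    Window k covers lengths 60(k-1)+1 .. 60k (so a 60-character SMILES lands
    in bin 1 and a 61-character one in bin 2); inputs longer than 600
    characters go to a flagged overflow bin.
    """
    if len(outcomes) != len(input_smiles):
        raise ValueError("outcomes/input lists differ in length")
    groups: dict[int, list[RoundTripOutcome]] = {}
    for o, smi in zip(outcomes, input_smiles):
        k = max(1, math.ceil(len(smi) / 60))
        if k > 10:
            k = 11
        groups.setdefault(k, []).append(o)
    bins = []
    for k in range(1, 12):
        members = groups.get(k, [])
        low, high = (60 * (k - 1) + 1 if k > 1 else 0), 60 * k
        overflow = k == 11
        if overflow:
            low, high = 601, -1
            if not members:
                continue
        if not members:
            bins.append(LengthBin(k, (low, high), 0, None, None, None))
            continue
        m = len(members)
        bins.append(LengthBin(
            k, (low, high), m,
            100.0 * sum(o.identical_name for o in members) / m,
            100.0 * sum(o.parse_error is None for o in members) / m,
            float(np.mean([o.tanimoto for o in members])),
            overflow=overflow,
        ))
    return bins


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_eval_tsv(path: str | Path):
    """Columns: reference_name <TAB> predicted_name [<TAB> reference_smiles]."""
    refs, preds, smiles = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            refs.append(parts[0])
            preds.append(parts[1])
            smiles.append(parts[2] if len(parts) > 2 else "")
    has_smiles = any(smiles)
    return refs, preds, (smiles if has_smiles else None)


def write_outcomes_tsv(outcomes: Sequence[RoundTripOutcome],
                       path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("predicted_name\tparsed_smiles\tparse_error\ttanimoto\t"
                 "identical_name\tidentical_structure\n")
        for o in outcomes:
            fh.write(f"{o.predicted_name}\t{o.parsed_smiles or ''}\t"
                     f"{o.parse_error or ''}\t{o.tanimoto:.4f}\t"
                     f"{int(o.identical_name)}\t{int(o.identical_structure)}\n")
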