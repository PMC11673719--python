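"""Curation of paired (SMILES, IUPAC name) datasets.

The pipeline standardises every structure to a canonical, kekulised,
stereochemistry-preserving SMILES string so that each unique compound maps to
exactly one input representation, filters over-long records, deduplicates on
the canonical structure, and serialises the result into size-bounded shards
that can be streamed during training.
"""

from __future__ import annotations

import gzip
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, rdBase
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

CANONICALIZER = f"rdkit-{rdBase.rdkitVersion}"


class CanonicalizationError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class PairRecord:
    """One (canonical SMILES, IUPAC name) training or test example."""

    smiles: str
    name: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not self.name:
            raise ValueError("name must be non-empty")
        for fieldname, value in (("smiles", self.smiles), ("name", self.name)):
            if "\t" in value or "\n" in value:
                raise ValueError(f"{fieldname} may not contain tabs or newlines")


@dataclass
class CorpusStats:
    record_count: int = 0
    max_smiles_length: int = 0
    max_name_length: int = 0
    unique_smiles_tokens: int = 0
    unique_name_tokens: int = 0


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical, kekulised, isomeric form of *smiles*.

    Aromatic rings are rewritten with explicit alternating bonds
    (``c1ccccc1`` -> ``C1=CC=CC=C1``); stereo markers are preserved.
    Idempotent: the output canonicalises to itself.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CanonicalizationError(smiles)
    return canonicalize_mol(mol)


def canonicalize_mol(mol: Chem.Mol) -> str:
    """Canonical kekulised isomeric SMILES for an RDKit molecule.

    The molecule is first reduced to its canonical aromatic form so that the
    subsequent kekulisation is independent of the input's resonance
    spelling: every Kekule spelling of one molecule maps to one string.
    """
    mol = Chem.Mol(mol)
    Chem.SanitizeMol(mol)
    canonical = Chem.MolFromSmiles(Chem.MolToSmiles(mol, isomericSmiles=True))
    Chem.Kekulize(canonical, clearAromaticFlags=True)
    return Chem.MolToSmiles(canonical, isomericSmiles=True, kekuleSmiles=True)


def filter_by_length(
    records: Sequence[PairRecord], max_smiles: int, max_name: int
) -> list[PairRecord]:
    """Keep records with ``len(smiles) <= max_smiles`` and ``len(name) <= max_name``.

    The bounds are inclusive: a 600-character SMILES survives a 600-character
    limit; only strictly longer strings are removed.  Order is preserved.
    """
    if max_smiles <= 0 or max_name <= 0:
        raise ValueError("length limits must be positive")
    return [
        r for r in records if len(r.smiles) <= max_smiles and len(r.name) <= max_name
    ]


def deduplicate(
    records: Sequence[PairRecord],
) -> tuple[list[PairRecord], dict[str, list[str]]]:
    """One record per canonical SMILES; first occurrence wins.

    Returns ``(kept, conflicts)`` where *conflicts* maps each SMILES that was
    seen with more than one distinct name to the full list of names seen, in
    order of first appearance.
    """
    kept: list[PairRecord] = []
    names_seen: dict[str, list[str]] = {}
    for rec in records:
        if rec.smiles not in names_seen:
            names_seen[rec.smiles] = [rec.name]
            kept.append(rec)
        elif rec.name not in names_seen[rec.smiles]:
            names_seen[rec.smiles].append(rec.name)
    conflicts = {s: names for s, names in names_seen.items() if len(names) > 1}
    return kept, conflicts


# ---------------------------------------------------------------------------
# TSV pair files: two columns, SMILES <TAB> name, optional third source tag.
# ---------------------------------------------------------------------------


def read_pairs(path: str | Path) -> list[PairRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected SMILES<TAB>name")
            tag = parts[2] if len(parts) > 2 else ""
            records.append(PairRecord(parts[0], parts[1], tag))
    return records


def write_pairs(records: Iterable[PairRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if rec.source_tag:
                fh.write(f"{rec.smiles}\t{rec.name}\t{rec.source_tag}\n")
            else:
                fh.write(f"{rec.smiles}\t{rec.name}\n")


# ---------------------------------------------------------------------------
# Shard store: framework-neutral length-prefixed record stream.
# Each record is a UTF-8 "smiles\tname\tsource_tag" payload preceded by a
# big-endian uint32 byte length.  Shards are numbered and size-bounded.
# ---------------------------------------------------------------------------

_LEN = struct.Struct(">I")


def _encode_record(rec: PairRecord) -> bytes:
    payload = f"{rec.smiles}\t{rec.name}\t{rec.source_tag}".encode()
    return _LEN.pack(len(payload)) + payload


def write_shards(
    records: Sequence[PairRecord],
    shard_budget: int,
    directory: str | Path,
    compress: bool = False,
    seed: int | None = None,
) -> dict:
    """Serialise *records* into numbered shards of at most *shard_budget* bytes.

    A single record larger than the budget still gets its own shard.  Returns
    the manifest (also written to ``manifest.json``): shard filenames, per-shard
    record counts, the canonicaliser version, and the creation seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".recs.gz" if compress else ".recs"
    shards: list[dict] = []
    buf: list[bytes] = []
    size = 0

    def flush() -> None:
        nonlocal buf, size
        if not buf:
            return
        fname = f"shard-{len(shards):05d}{ext}"
        raw = b"".join(buf)
        data = gzip.compress(raw) if compress else raw
        (directory / fname).write_bytes(data)
        shards.append({"file": fname, "records": len(buf)})
        buf, size = [], 0

    for rec in records:
        blob = _encode_record(rec)
        if buf and size + len(blob) > shard_budget:
            flush()
        buf.append(blob)
        size += len(blob)
        if size > shard_budget:  # single oversized record
            flush()
    flush()

    manifest = {
        "format": "length-prefixed-v1",
        "compressed": compress,
        "canonicalizer": CANONICALIZER,
        "seed": seed,
        "shards": shards,
        "record_count": sum(s["records"] for s in shards),
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_shards(directory: str | Path) -> Iterator[PairRecord]:
    """Stream records back in manifest order; inverse of :func:`write_shards`."""
    directory = Path(directory)
    with open(directory / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    for shard in manifest["shards"]:
        data = (directory / shard["file"]).read_bytes()
        if manifest["compressed"]:
            data = gzip.decompress(data)
        offset = 0
        for _ in range(shard["records"]):
            (n,) = _LEN.unpack_from(data, offset)
            offset += _LEN.size
            smiles, name, tag = data[offset : offset + n].decode().split("\t")
            offset += n
            yield PairRecord(smiles, name, tag)


def compute_stats(records: Sequence[PairRecord], smiles_tokens, name_tokens) -> CorpusStats:
    """Corpus summary; token counts use the supplied tokeniser callables."""
    stats = CorpusStats(record_count=len(records))
    smi_vocab: set[str] = set()
    name_vocab: set[str] = set()
    for rec in records:
        stats.max_smiles_length = max(stats.max_smiles_length, len(rec.smiles))
        stats.max_name_length = max(stats.max_name_length, len(rec.name))
        smi_vocab.update(smiles_tokens(rec.smiles))
        name_vocab.update(name_tokens(rec.name))
    stats.unique_smiles_tokens = len(smi_vocab)
    stats.unique_name_tokens = len(name_vocab)
    return stats
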