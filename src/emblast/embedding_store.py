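"""Sequence records, per-residue embedding matrices and the on-disk database.

An :class:`EmbeddingDatabase` is an ordered collection of
(embedding matrix, sequence record) pairs sharing one embedding dimension.
On disk it is a directory holding a single ``.npz`` archive of named
float32 arrays, a tab-separated index (id, length, description), the
sequences as FASTA, and a JSON metadata file; prefilter chunk vectors
computed at build time are stored in the same archive.

Embedding *backends* turn sequences into matrices.  The synthetic backend
(unit-norm isotropic rows, deterministic in the seed) makes the whole tool
testable without any model download; the ProtT5 backend wraps an external
protein language model and is entirely optional.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Protocol, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "EmbeddingMatrix",
    "EmbeddingDatabase",
    "EmbeddingBackend",
    "SyntheticBackend",
    "ProtT5Backend",
    "read_fasta",
    "write_fasta",
    "compute_embeddings",
    "save_database",
    "load_database",
]

#: the 20 standard amino acids plus X (unknown residue)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_ARCHIVE = "embeddings.npz"
_INDEX = "index.tsv"
_FASTA = "sequences.fasta"
_META = "meta.json"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with a unique identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = sorted(set(self.sequence) - VALID_RESIDUES)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains unsupported characters {bad}; "
                "only the 20 standard amino acids and X are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding of one sequence: one row per residue."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(
                f"embedding {self.id!r} must be a 2-D matrix, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"embedding {self.id!r} contains non-finite values")

    @property
    def n(self) -> int:
        """Number of residues."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Embedding dimension."""
        return self.values.shape[1]


class EmbeddingBackend(Protocol):
    """Anything that maps an amino-acid sequence to an n x m matrix."""

    name: str

    def embed(self, record: SequenceRecord) -> np.ndarray: ...


class SyntheticBackend:
    """Deterministic random embeddings: isotropic unit-norm rows.

    Each record's rows are drawn from a stream seeded by (seed, crc32(id)),
    so a record's matrix depends only on its id, its length, the dimension
    and the seed -- rerunning with the same seed reproduces the archive
    bit for bit.
    """

    name = "synthetic"

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        self.dim = int(dim)
        self.seed = int(seed)

    def embed(self, record: SequenceRecord) -> np.ndarray:
        rng = np.random.default_rng([self.seed, zlib.crc32(record.id.encode())])
        rows = rng.standard_normal((len(record), self.dim))
        rows /= np.linalg.norm(rows, axis=1, keepdims=True)
        return rows.astype(np.float32)


class ProtT5Backend:
    """Embeddings from the ProtT5-XL encoder (optional, needs torch + transformers).

    Produces one 1024-dimensional vector per residue.  The model weights
    are large; when the dependencies or weights are unavailable the
    constructor fails with instructions to use precomputed embeddings or
    the synthetic backend instead.
    """

    name = "prott5"
    dim = 1024
    model_id = "Rostlab/prot_t5_xl_half_uniref50-enc"

    def __init__(self, device: str = "cpu"):
        try:
            import torch  # noqa: F401
            from transformers import T5EncoderModel, T5Tokenizer
        except ImportError as exc:  # pragma: no cover - depends on extras
            raise ImportError(
                "the ProtT5 backend needs the optional 'plm' extra "
                "(pip install emblast[plm]); use precomputed embeddings or "
                "the synthetic backend otherwise"
            ) from exc
        self._torch = torch
        self.device = device
        self.tokenizer = T5Tokenizer.from_pretrained(self.model_id, do_lower_case=False)
        self.model = T5EncoderModel.from_pretrained(self.model_id).to(device).eval()

    def embed(self, record: SequenceRecord) -> np.ndarray:  # pragma: no cover
        spaced = " ".join(record.sequence)
        ids = self.tokenizer(spaced, return_tensors="pt").to(self.device)
        with self._torch.no_grad():
            out = self.model(**ids).last_hidden_state[0]
        # drop the </s> token appended by the tokenizer
        return out[: len(record)].cpu().numpy().astype(np.float32)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into sequence records.

    Sequences are uppercased and whitespace-stripped; duplicate ids and
    files whose first non-blank line is not a header are rejected.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {bio.id!r}")
        seen.add(bio.id)
        seq = "".join(str(bio.seq).split()).upper()
        desc = bio.description[len(bio.id):].strip()
        records.append(SequenceRecord(id=bio.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (round-trips with :func:`read_fasta`)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def compute_embeddings(
    records: Sequence[SequenceRecord], backend: EmbeddingBackend
) -> list[EmbeddingMatrix]:
    """Embed every record with the given backend (one matrix per record)."""
    out = []
    for rec in records:
        values = backend.embed(rec)
        if values.shape[0] != len(rec):
            raise ValueError(
                f"backend {backend.name!r} returned {values.shape[0]} rows for "
                f"{rec.id!r} of length {len(rec)}"
            )
        out.append(EmbeddingMatrix(id=rec.id, values=values))
    return out


@dataclass
class EmbeddingDatabase:
    """Ordered (by id) collection of embeddings with their sequence records.

    ``chunks`` optionally carries precomputed prefilter chunk vectors
    (built by :func:`emblast.prefilter.add_chunk_index`) so query-time
    screening reuses the build-time windowing.
    """

    entries: dict[str, tuple[EmbeddingMatrix, SequenceRecord]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    chunks: dict[str, "object"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = dict(sorted(self.entries.items()))
        self._validate()

    def _validate(self) -> None:
        dims = set()
        for key, (emb, rec) in self.entries.items():
            if key != emb.id or key != rec.id:
                raise ValueError(f"database key {key!r} does not match entry ids")
            if emb.n != len(rec):
                raise ValueError(
                    f"entry {key!r}: embedding has {emb.n} rows but sequence "
                    f"has {len(rec)} residues"
                )
            dims.add(emb.m)
        if len(dims) > 1:
            raise ValueError(f"mixed embedding dimensions in database: {sorted(dims)}")

    @property
    def embedding_dim(self) -> int | None:
        for emb, _ in self.entries.values():
            return emb.m
        return None

    def add(self, emb: EmbeddingMatrix, rec: SequenceRecord) -> None:
        if emb.id != rec.id:
            raise ValueError(f"embedding id {emb.id!r} != record id {rec.id!r}")
        if emb.id in self.entries:
            raise ValueError(f"duplicate database id {emb.id!r}")
        dim = self.embedding_dim
        if dim is not None and emb.m != dim:
            raise ValueError(
                f"entry {emb.id!r} has dimension {emb.m}, database has {dim}"
            )
        if emb.n != len(rec):
            raise ValueError(
                f"entry {emb.id!r}: {emb.n} embedding rows vs {len(rec)} residues"
            )
        self.entries[emb.id] = (emb, rec)
        self.entries = dict(sorted(self.entries.items()))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> tuple[EmbeddingMatrix, SequenceRecord]:
        return self.entries[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    @classmethod
    def from_pairs(
        cls,
        embeddings: Sequence[EmbeddingMatrix],
        records: Sequence[SequenceRecord],
        metadata: Mapping | None = None,
    ) -> "EmbeddingDatabase":
        recmap = {r.id: r for r in records}
        entries = {}
        for emb in embeddings:
            if emb.id not in recmap:
                raise ValueError(f"no sequence record for embedding {emb.id!r}")
            entries[emb.id] = (emb, recmap[emb.id])
        return cls(entries=entries, metadata=dict(metadata or {}))


def save_database(db: EmbeddingDatabase, path: str | Path) -> None:
    """Write a database directory: npz archive + TSV index + FASTA + metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    lines = ["id\tlength\tdescription"]
    for key, (emb, rec) in db.entries.items():
        arrays[f"emb/{key}"] = emb.values.astype(np.float32)
        lines.append(f"{key}\t{emb.n}\t{rec.description}")
    for key, chunk in db.chunks.items():
        arrays[f"chunk/{key}"] = np.asarray(chunk.vectors, dtype=np.float32)
        arrays[f"chunkpos/{key}"] = np.asarray(chunk.origin_positions, dtype=np.int64)
    np.savez(path / _ARCHIVE, **arrays)
    (path / _INDEX).write_text("\n".join(lines) + "\n")
    write_fasta([rec for _, rec in db.entries.values()], path / _FASTA)
    (path / _META).write_text(json.dumps(db.metadata, indent=2, sort_keys=True) + "\n")


def load_database(path: str | Path) -> EmbeddingDatabase:
    """Load a database directory written by :func:`save_database`."""
    from emblast.prefilter import ChunkMatrix

    path = Path(path)
    for name in (_ARCHIVE, _INDEX, _FASTA, _META):
        if not (path / name).exists():
            raise FileNotFoundError(f"{path}: missing database file {name}")
    index_lines = (path / _INDEX).read_text().splitlines()
    if not index_lines or index_lines[0].split("\t") != ["id", "length", "description"]:
        raise ValueError(f"{path}: corrupted index header")
    lengths: dict[str, int] = {}
    for line in index_lines[1:]:
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}: corrupted index line {line!r}")
        lengths[fields[0]] = int(fields[1])
    if (path / _FASTA).read_text().strip():
        records = {r.id: r for r in read_fasta(path / _FASTA)}
    else:  # empty database round-trips
        records = {}
    metadata = json.loads((path / _META).read_text())

    entries: dict[str, tuple[EmbeddingMatrix, SequenceRecord]] = {}
    chunks: dict[str, ChunkMatrix] = {}
    with np.load(path / _ARCHIVE) as npz:
        for name in npz.files:
            kind, _, key = name.partition("/")
            if kind == "emb":
                if key not in records:
                    raise ValueError(f"{path}: embedding {key!r} has no sequence record")
                values = npz[name]
                if key in lengths and values.shape[0] != lengths[key]:
                    raise ValueError(
                        f"{path}: index says {lengths[key]} residues for {key!r}, "
                        f"archive has {values.shape[0]} rows"
                    )
                entries[key] = (EmbeddingMatrix(id=key, values=values), records[key])
        for name in npz.files:
            kind, _, key = name.partition("/")
            if kind == "chunk":
                chunks[key] = ChunkMatrix(
                    vectors=npz[name],
                    window=int(metadata.get("prefilter_window", 30)),
                    stride=int(metadata.get("prefilter_stride", 15)),
                    origin_positions=npz[f"chunkpos/{key}"].tolist(),
                )
    missing = set(records) - set(entries)
    if missing:
        raise ValueError(f"{path}: sequences without embeddings: {sorted(missing)}")
    db = EmbeddingDatabase(entries=entries, metadata=metadata)
    db.chunks = chunks
    return db
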