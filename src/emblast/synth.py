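"""Synthetic embedding fixtures: random backgrounds and planted homology.

Real language-model embeddings are expensive to compute; everything
downstream of row normalization only sees unit-norm row vectors, so
isotropic unit-norm random rows are a faithful test substrate.  Homology
is *planted* by copying a query segment into a fresh background and
mixing each copied row with orthogonalized noise:

    row = s * q + sqrt(1 - s^2) * z_perp

where q is the (unit) query row and z_perp unit noise orthogonal to q,
so the cosine between corresponding rows is exactly the requested signal
s.  Ground truth -- which residue pairs are homologous -- is therefore
known by construction.

Default study conditions used throughout the test-bench: embedding
dimension 64, sequence length 150, planted segment length 40, signal
0.7 (background cosines concentrate near 0 with spread 1/sqrt(64)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from emblast.embedding_store import EmbeddingDatabase, EmbeddingMatrix, SequenceRecord

__all__ = [
    "PlantSpec",
    "BenchmarkData",
    "random_embedding",
    "random_sequence",
    "plant_homology",
    "make_planted_pair",
    "make_benchmark_db",
    "DEFAULT_DIM",
    "DEFAULT_LENGTH",
    "DEFAULT_SEGMENT",
    "DEFAULT_SIGNAL",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_DIM = 64
DEFAULT_LENGTH = 150
DEFAULT_SEGMENT = 40
DEFAULT_SIGNAL = 0.7


@dataclass(frozen=True)
class PlantSpec:
    """Where and how strongly to plant a homologous segment."""

    query_region: tuple[int, int]  # (start, length)
    target_region: tuple[int, int]  # (start, length), same length
    signal: float  # expected within-segment cosine, in [0, 1]
    seed: int
    target_length: int = DEFAULT_LENGTH

    def __post_init__(self) -> None:
        (qs, ql), (ts, tl) = self.query_region, self.target_region
        if ql != tl or ql < 1:
            raise ValueError("query and target regions must have equal length >= 1")
        if qs < 0 or ts < 0 or ts + tl > self.target_length:
            raise ValueError("planted region outside sequence bounds")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError(f"signal must be in [0, 1], got {self.signal}")

    @property
    def pairs(self) -> set[tuple[int, int]]:
        """Ground-truth aligned residue pairs implied by the plant."""
        (qs, ql), (ts, _) = self.query_region, self.target_region
        return {(qs + off, ts + off) for off in range(ql)}


def random_embedding(n: int, m: int, seed: int, id: str = "synthetic") -> EmbeddingMatrix:
    """Isotropic unit-norm random embedding, deterministic in the seed."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = np.random.default_rng(seed)
    rows = rng.standard_normal((n, m))
    rows /= np.linalg.norm(rows, axis=1, keepdims=True)
    return EmbeddingMatrix(id=id, values=rows)


def random_sequence(n: int, seed: int, id: str = "synthetic") -> SequenceRecord:
    """Uniform random amino-acid companion sequence for rendering."""
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(AMINO_ACIDS), size=n)
    return SequenceRecord(id=id, sequence="".join(letters))


def plant_homology(
    query: EmbeddingMatrix, spec: PlantSpec, id: str = "homolog"
) -> EmbeddingMatrix:
    """Fresh random embedding with a segment homologous to the query.

    Rows of the target region mix the corresponding query rows with
    orthogonalized unit noise so that each within-segment cosine equals
    ``spec.signal`` exactly; the rest is background.
    """
    (qs, ql), (ts, _) = spec.query_region, spec.target_region
    if qs + ql > query.n:
        raise ValueError("query region outside the query embedding")
    rng = np.random.default_rng(spec.seed)
    target = rng.standard_normal((spec.target_length, query.m))
    target /= np.linalg.norm(target, axis=1, keepdims=True)
    s = spec.signal
    qrows = np.asarray(query.values, dtype=np.float64)
    qnorm = qrows / np.linalg.norm(qrows, axis=1, keepdims=True)
    for off in range(ql):
        q = qnorm[qs + off]
        z = rng.standard_normal(query.m)
        z -= (z @ q) * q
        z /= np.linalg.norm(z)
        target[ts + off] = s * q + np.sqrt(1.0 - s * s) * z
    return EmbeddingMatrix(id=id, values=target)


def make_planted_pair(
    seed: int,
    m: int = DEFAULT_DIM,
    length: int = DEFAULT_LENGTH,
    segment_length: int = DEFAULT_SEGMENT,
    signal: float = DEFAULT_SIGNAL,
):
    """One query/target pair with a planted segment at random offsets.

    Returns (query, query_record, target, target_record, spec); the
    ground-truth residue pairs are ``spec.pairs``.
    """
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    query = random_embedding(length, m, child(), id="query")
    query_record = random_sequence(length, child(), id="query")
    qs = int(rng.integers(0, length - segment_length + 1))
    ts = int(rng.integers(0, length - segment_length + 1))
    spec = PlantSpec(
        query_region=(qs, segment_length),
        target_region=(ts, segment_length),
        signal=signal,
        seed=child(),
        target_length=length,
    )
    target = plant_homology(query, spec, id="target")
    target_record = random_sequence(length, child(), id="target")
    return query, query_record, target, target_record, spec


@dataclass
class BenchmarkData:
    """A synthetic search benchmark: query, database, and ground truth."""

    query: EmbeddingMatrix
    query_record: SequenceRecord
    database: EmbeddingDatabase
    ground_truth: dict[str, set[tuple[int, int]]]


def make_benchmark_db(
    n_decoys: int = 50,
    n_homologs: int = 5,
    seed: int = 0,
    m: int = DEFAULT_DIM,
    query_length: int = DEFAULT_LENGTH,
    target_length: int = DEFAULT_LENGTH,
    segment_length: int = DEFAULT_SEGMENT,
    signal: float = DEFAULT_SIGNAL,
    decoy_length_range: tuple[int, int] = (100, 200),
) -> BenchmarkData:
    """Build a decoys-plus-planted-homologs database for one query.

    Each homolog carries one planted segment copied from a random query
    region at a random target offset; decoys are pure background.  The
    ground-truth table maps each homolog id to its planted residue-pair
    set.  Fully deterministic in the seed.
    """
    if n_decoys < 0 or n_homologs < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    query = random_embedding(query_length, m, child(), id="query")
    query_record = random_sequence(query_length, child(), id="query")

    db = EmbeddingDatabase(metadata={"backend": "synthetic", "seed": int(seed)})
    truth: dict[str, set[tuple[int, int]]] = {}
    width = max(3, len(str(max(n_decoys, n_homologs, 1))))
    for idx in range(n_homologs):
        hid = f"homolog_{idx:0{width}d}"
        qs = int(rng.integers(0, query_length - segment_length + 1))
        ts = int(rng.integers(0, target_length - segment_length + 1))
        spec = PlantSpec(
            query_region=(qs, segment_length),
            target_region=(ts, segment_length),
            signal=signal,
            seed=child(),
            target_length=target_length,
        )
        emb = plant_homology(query, spec, id=hid)
        db.add(emb, random_sequence(target_length, child(), id=hid))
        truth[hid] = spec.pairs
    for idx in range(n_decoys):
        did = f"decoy_{idx:0{width}d}"
        n = int(rng.integers(decoy_length_range[0], decoy_length_range[1] + 1))
        db.add(random_embedding(n, m, child(), id=did), random_sequence(n, child(), id=did))
    return BenchmarkData(
        query=query, query_record=query_record, database=db, ground_truth=truth
    )


def write_ground_truth(truth: dict[str, set[tuple[int, int]]], path: str | Path) -> None:
    """Tab-separated ground truth: target_id, query_index, target_index."""
    lines = ["# target_id\tquery_index\ttarget_index"]
    for tid in sorted(truth):
        for q, t in sorted(truth[tid]):
            lines.append(f"{tid}\t{q}\t{t}")
    Path(path).write_text("\n".join(lines) + "\n")
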