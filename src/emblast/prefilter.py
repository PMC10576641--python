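"""Chunked cosine-similarity prefilter for database search.

Averaging a whole protein's residue embeddings into one vector is fast
but blurs away local similarity.  As a middle ground, the per-residue
embedding is treated as a 2-D image and cut into windows along the
sequence dimension (30 residues by default, full embedding width); each
window is flattened and unit-normalized.  The prefilter score of a
sequence pair is the maximum cosine similarity over all window pairs, so
one strongly similar region suffices to pass a candidate on to full
alignment.  Candidate selection keeps, per query, the database entries
scoring at or above a percentile of the score distribution (90th by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from emblast.embedding_store import EmbeddingDatabase, EmbeddingMatrix

__all__ = [
    "ChunkMatrix",
    "PrefilterResult",
    "chunk_embedding",
    "prefilter_score",
    "select_candidates",
    "add_chunk_index",
]

DEFAULT_PREFILTER_WINDOW = 30
DEFAULT_PREFILTER_STRIDE = 15
DEFAULT_PERCENTILE = 90.0


@dataclass
class ChunkMatrix:
    """Flattened, unit-normalized embedding windows of one sequence."""

    vectors: np.ndarray  # (n_windows, window * m), unit rows
    window: int
    stride: int
    origin_positions: list[int]


@dataclass(frozen=True)
class PrefilterResult:
    """Prefilter score of one database entry against the current query."""

    target_id: str
    score: float


def chunk_embedding(
    E: EmbeddingMatrix,
    window: int = DEFAULT_PREFILTER_WINDOW,
    stride: int = DEFAULT_PREFILTER_STRIDE,
) -> ChunkMatrix:
    """Cut an embedding into flattened windows along the sequence dimension.

    Windows start at 0, stride, 2*stride, ... as long as a full window
    fits; a sequence shorter than the window yields a single window
    covering the whole sequence.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    values = np.asarray(E.values, dtype=np.float64)
    n = values.shape[0]
    if n < window:
        starts = [0]
        rows = [values.reshape(-1)]
    else:
        starts = list(range(0, n - window + 1, stride))
        rows = [values[s : s + window].reshape(-1) for s in starts]
    vectors = np.vstack(rows)
    norms = np.linalg.norm(vectors, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        raise ValueError(
            f"embedding {E.id!r}: window(s) starting at "
            f"{[starts[b] for b in bad]} have zero norm"
        )
    vectors /= norms[:, None]
    return ChunkMatrix(vectors=vectors, window=window, stride=stride, origin_positions=starts)


def prefilter_score(query_chunks: ChunkMatrix, target_chunks: ChunkMatrix) -> float:
    """Maximum cosine similarity over all query/target window pairs."""
    q, t = query_chunks.vectors, target_chunks.vectors
    if q.shape[1] != t.shape[1]:
        # one sequence was shorter than the window, so its single chunk is
        # narrower; zero-pad it (rows stay unit norm, dot products compare
        # the overlapping window prefix)
        width = max(q.shape[1], t.shape[1])
        if q.shape[1] < width:
            q = np.pad(q, ((0, 0), (0, width - q.shape[1])))
        else:
            t = np.pad(t, ((0, 0), (0, width - t.shape[1])))
    return float((q @ t.T).max())


def select_candidates(
    scores: Sequence[PrefilterResult], percentile: float = DEFAULT_PERCENTILE
) -> set[str]:
    """Ids scoring at or above the given percentile of this query's scores.

    Nearest-rank percentile on the score list; ties at the cutoff are all
    kept.  Percentile 0 keeps everything, percentile 100 only the best
    score (and its ties).
    """
    if not scores:
        raise ValueError("cannot select candidates from an empty score list")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    values = np.array([r.score for r in scores])
    cutoff = float(np.percentile(values, percentile, method="higher"))
    return {r.target_id for r in scores if r.score >= cutoff}


def select_by_threshold(scores: Iterable[PrefilterResult], threshold: float) -> set[str]:
    """Absolute-threshold variant: ids whose score is >= threshold."""
    return {r.target_id for r in scores if r.score >= threshold}


def add_chunk_index(
    db: EmbeddingDatabase,
    window: int = DEFAULT_PREFILTER_WINDOW,
    stride: int = DEFAULT_PREFILTER_STRIDE,
) -> EmbeddingDatabase:
    """Precompute and attach chunk vectors for every database entry.

    The window/stride are recorded in the database metadata so query-time
    chunking always matches build-time chunking.
    """
    db.chunks = {
        key: chunk_embedding(emb, window=window, stride=stride)
        for key, (emb, _) in db.entries.items()
    }
    db.metadata["prefilter_window"] = int(window)
    db.metadata["prefilter_stride"] = int(stride)
    return db
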