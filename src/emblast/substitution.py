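"""Context-dependent substitution matrices from per-residue embeddings.

Instead of a fixed 20x20 amino-acid table, every query/target residue
pair (i, j) is scored by the cosine similarity of its embedding vectors:
rows are first scaled to unit Euclidean norm, after which the full
similarity grid is a single matrix product  S = E_q E_t^T  with every
element in [-1, 1].  The standard deviation of S over all elements
(``sigma``) later sets the capture threshold for local alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from emblast.embedding_store import EmbeddingMatrix

__all__ = ["SubstitutionMatrix", "normalize_rows", "substitution_matrix"]

_MIN_ROW_NORM = 1e-12


@dataclass
class SubstitutionMatrix:
    """Dense residue-by-residue cosine-similarity grid for one sequence pair."""

    values: np.ndarray  # n_query x n_target, float64, clipped to [-1, 1]
    sigma: float  # population standard deviation of all elements
    query_id: str = ""
    target_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalize_rows(E: EmbeddingMatrix) -> EmbeddingMatrix:
    """Scale every embedding row to unit Euclidean norm.

    Raises if any row norm is below 1e-12 (a degenerate embedding for
    which cosine similarity is undefined).
    """
    values = np.asarray(E.values, dtype=np.float64)
    norms = np.linalg.norm(values, axis=1)
    bad = np.flatnonzero(norms < _MIN_ROW_NORM)
    if bad.size:
        raise ValueError(
            f"embedding {E.id!r}: row(s) {bad.tolist()} have near-zero norm; "
            "cannot normalize a degenerate embedding"
        )
    return EmbeddingMatrix(id=E.id, values=values / norms[:, None])


def substitution_matrix(
    Eq_norm: EmbeddingMatrix, Et_norm: EmbeddingMatrix
) -> SubstitutionMatrix:
    """Cosine similarity of every query/target residue pair.

    Both inputs must be row-normalized (see :func:`normalize_rows`); the
    product is clipped to [-1, 1] to absorb floating-point excursions
    before any downstream thresholding.
    """
    if Eq_norm.m != Et_norm.m:
        raise ValueError(
            f"embedding dimension mismatch: {Eq_norm.id!r} has {Eq_norm.m}, "
            f"{Et_norm.id!r} has {Et_norm.m}"
        )
    q = np.asarray(Eq_norm.values, dtype=np.float64)
    t = np.asarray(Et_norm.values, dtype=np.float64)
    for emb, arr in ((Eq_norm, q), (Et_norm, t)):
        norms = np.linalg.norm(arr, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"embedding {emb.id!r} is not row-normalized")
    values = np.clip(q @ t.T, -1.0, 1.0)
    return SubstitutionMatrix(
        values=values,
        sigma=float(values.std()),
        query_id=Eq_norm.id,
        target_id=Et_norm.id,
    )


def dump_matrix(S: SubstitutionMatrix, path) -> None:
    """Debug dump: tab-separated grid, query residues as rows."""
    np.savetxt(path, S.values, delimiter="\t", fmt="%.6f")
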