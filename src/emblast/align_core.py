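"""Alignment engine: gapless cumulative scoring, multi-start traceback,
moving-average local-alignment extraction, and zero-gap global alignment.

The local mode adapts Smith-Waterman to cosine-similarity substitution
values: because dissimilar regions already score near zero or negative,
no gap penalty is used, and the cumulative matrix is not truncated at
zero.  Rather than tracing back from the single best cell, candidate
paths are started from every cell on the bottom and right borders of the
cumulative matrix and walked greedily toward the origin; each path is
then scanned with a moving average over its substitution values, and
maximal stretches whose smoothed score clears a threshold expressed in
multiples of the substitution matrix's standard deviation (2 sigma by
default) are reported as local alignments.

Global mode is Needleman-Wunsch with the similarity table replaced by
the embedding substitution matrix and the gap penalty set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from emblast.substitution import SubstitutionMatrix

__all__ = [
    "ScoringMatrix",
    "AlignmentPath",
    "LocalAlignment",
    "GlobalAlignment",
    "scoring_matrix",
    "traceback_paths",
    "extract_local_alignments",
    "filter_alignments",
    "global_align",
    "render_alignment",
]

#: default moving-average window (cells) for local-alignment extraction
DEFAULT_WINDOW = 15
#: default capture threshold in units of the substitution-matrix sigma
DEFAULT_SIGMA_FACTOR = 2.0


@dataclass
class ScoringMatrix:
    """Cumulative (n+1) x (k+1) score matrix; first row and column are zero."""

    values: np.ndarray


@dataclass
class AlignmentPath:
    """One candidate traceback path: monotone cells through the substitution
    matrix (0-based, N-to-C order) with the substitution value at each cell."""

    cells: np.ndarray  # (L, 2) int64
    per_cell_scores: np.ndarray  # (L,) float64

    def __len__(self) -> int:
        return self.cells.shape[0]


@dataclass
class LocalAlignment:
    """A contiguous high-scoring subpath; score is the mean substitution
    value over its cells (dimensionless, length-comparable)."""

    cells: np.ndarray
    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    gapped_query: str = ""
    gapped_target: str = ""

    def __len__(self) -> int:
        return self.cells.shape[0]


@dataclass
class GlobalAlignment:
    """End-to-end alignment of both sequences.

    ``columns`` is the authoritative representation: one
    (query_index | None, target_index | None) pair per alignment column,
    covering every residue of both sequences (None marks a gap).  ``cells``
    is the unit-step cell path over the span from the first to the last
    match column; ``score`` is the mean substitution value over match
    columns and ``total_score`` their sum (the optimum of the zero-gap
    dynamic program).
    """

    columns: list
    cells: np.ndarray
    score: float
    total_score: float
    gapped_query: str = ""
    gapped_target: str = ""

    @property
    def match_cells(self) -> list[tuple[int, int]]:
        return [(q, t) for q, t in self.columns if q is not None and t is not None]


@njit(cache=True)
def _fill(S):  # pragma: no cover - exercised via scoring_matrix
    n, k = S.shape
    H = np.zeros((n + 1, k + 1))
    for i in range(1, n + 1):
        for j in range(1, k + 1):
            best = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j]
            left = H[i, j - 1]
            if up > best:
                best = up
            if left > best:
                best = left
            H[i, j] = best
    return H


@njit(cache=True)
def _walk(H, i0, j0, out):  # pragma: no cover - exercised via traceback_paths
    """Greedy walk toward the origin; returns the number of cells written.

    Cells (in H coordinates) are recorded C-to-N; a cell with non-positive
    cumulative score never enters the path.  Ties prefer the diagonal
    predecessor, then the vertical one (substitutions over gaps).
    """
    idx = 0
    i, j = i0, j0
    while i >= 1 and j >= 1:
        if H[i, j] <= 0.0:
            break
        out[idx, 0] = i
        out[idx, 1] = j
        idx += 1
        diag = H[i - 1, j - 1]
        up = H[i - 1, j]
        left = H[i, j - 1]
        if diag >= up and diag >= left:
            i -= 1
            j -= 1
        elif up >= left:
            i -= 1
        else:
            j -= 1
    return idx


def scoring_matrix(S: SubstitutionMatrix) -> ScoringMatrix:
    """Fill the cumulative score matrix.

    h[i][j] = max(h[i-1][j-1] + s[i-1][j-1], h[i-1][j], h[i][j-1]) with a
    zero first row and column; gap moves cost nothing and values are not
    truncated at zero.
    """
    values = np.ascontiguousarray(S.values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("substitution matrix contains non-finite values")
    return ScoringMatrix(values=_fill(values))


def traceback_paths(H: ScoringMatrix, S: SubstitutionMatrix) -> list[AlignmentPath]:
    """Candidate alignment paths from every bottom/right border start.

    For sequences of length n and k there are n + k - 1 distinct starts
    (the corner cell is shared).  Each walk follows the best predecessor
    until the cumulative score drops to zero or an edge is reached; the
    collected cells are mapped into substitution-matrix coordinates,
    reversed into N-to-C order, and exact duplicates are discarded.
    """
    Hv = H.values
    n, k = Hv.shape[0] - 1, Hv.shape[1] - 1
    if S.values.shape != (n, k):
        raise ValueError("scoring matrix shape inconsistent with substitution matrix")
    starts = [(n, j) for j in range(1, k + 1)] + [(i, k) for i in range(1, n)]
    buf = np.empty((n + k, 2), dtype=np.int64)
    paths: list[AlignmentPath] = []
    seen: set[bytes] = set()
    for i0, j0 in starts:
        length = _walk(Hv, i0, j0, buf)
        if length == 0:
            continue
        cells = buf[:length][::-1] - 1  # H coords -> S coords, N-to-C order
        key = cells.tobytes()
        if key in seen:
            continue
        seen.add(key)
        cells = np.ascontiguousarray(cells)
        scores = S.values[cells[:, 0], cells[:, 1]]
        paths.append(AlignmentPath(cells=cells, per_cell_scores=np.asarray(scores)))
    return paths


def _smoothed(scores: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows are clipped at the path ends."""
    ones = np.ones(len(scores))
    kernel = np.ones(window)
    return np.convolve(scores, kernel, mode="same") / np.convolve(ones, kernel, mode="same")


def _make_local(cells: np.ndarray, scores: np.ndarray) -> LocalAlignment:
    return LocalAlignment(
        cells=np.ascontiguousarray(cells),
        score=float(scores.mean()),
        query_start=int(cells[0, 0]),
        query_end=int(cells[-1, 0]),
        target_start=int(cells[0, 1]),
        target_end=int(cells[-1, 1]),
    )


def extract_local_alignments(
    path: AlignmentPath,
    sigma: float,
    window: int = DEFAULT_WINDOW,
    sigma_factor: float = DEFAULT_SIGMA_FACTOR,
) -> list[LocalAlignment]:
    """Capture high-scoring subpaths of one traceback path.

    The path's substitution values are smoothed with a centered moving
    average of the given window; maximal runs of positions whose smoothed
    score reaches ``sigma_factor * sigma`` become local alignments.  A
    path shorter than the window is kept whole if its mean clears the
    threshold.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    L = len(path)
    if L == 0:
        return []
    threshold = sigma_factor * sigma
    scores = path.per_cell_scores
    if L < window:
        if scores.mean() >= threshold:
            return [_make_local(path.cells, scores)]
        return []
    mask = _smoothed(scores, window) >= threshold
    out: list[LocalAlignment] = []
    pos = 0
    while pos < L:
        if not mask[pos]:
            pos += 1
            continue
        end = pos
        while end + 1 < L and mask[end + 1]:
            end += 1
        out.append(_make_local(path.cells[pos : end + 1], scores[pos : end + 1]))
        pos = end + 1
    return out


def filter_alignments(alignments: list[LocalAlignment]) -> list[LocalAlignment]:
    """Collapse redundant local alignments from different path starts.

    Exact duplicates (identical cell ranges) are removed; among
    alignments sharing more than half of their cells (relative to the
    shorter one) only the most significant is kept.  Significance for
    this redundancy pass is the summed substitution score (mean x
    length), so a long alignment is not displaced by a one-cell fragment
    of itself with a higher mean.  Output is sorted by descending mean
    score, ties broken by coordinates for determinism.
    """
    ordered = sorted(
        alignments,
        key=lambda a: (-a.score * len(a), -len(a), a.query_start, a.target_start),
    )
    kept: list[LocalAlignment] = []
    kept_sets: list[set[tuple[int, int]]] = []
    for aln in ordered:
        cellset = {(int(i), int(j)) for i, j in aln.cells}
        redundant = False
        for other in kept_sets:
            shared = len(cellset & other)
            if shared > 0.5 * min(len(cellset), len(other)):
                redundant = True
                break
        if not redundant:
            kept.append(aln)
            kept_sets.append(cellset)
    kept.sort(key=lambda a: (-a.score, a.query_start, a.target_start))
    return kept


def global_align(S: SubstitutionMatrix) -> GlobalAlignment:
    """Needleman-Wunsch with zero gap penalty on the substitution matrix.

    The fill is the same recurrence as the local cumulative matrix; the
    traceback starts at the bottom-right corner and ends at the origin,
    preferring diagonal moves, so every residue of both sequences is
    covered by a match or a gap column.
    """
    n, k = S.values.shape
    if n == 0 or k == 0:
        raise ValueError("cannot globally align an empty substitution matrix")
    Sv = np.ascontiguousarray(S.values, dtype=np.float64)
    G = _fill(Sv)
    eps = 1e-12
    i, j = n, k
    rev_cols: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and G[i, j] <= G[i - 1, j - 1] + Sv[i - 1, j - 1] + eps:
            rev_cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and (j == 0 or G[i, j] <= G[i - 1, j] + eps):
            rev_cols.append((i - 1, None))
            i -= 1
        else:
            rev_cols.append((None, j - 1))
            j -= 1
    columns = rev_cols[::-1]
    matches = [(q, t) for q, t in columns if q is not None and t is not None]
    if matches:
        scores = np.array([Sv[q, t] for q, t in matches])
        score, total = float(scores.mean()), float(scores.sum())
    else:  # possible only if every substitution value is <= 0
        score, total = 0.0, 0.0
    cells = _columns_to_cells(columns)
    return GlobalAlignment(
        columns=columns, cells=cells, score=score, total_score=total
    )


def _columns_to_cells(columns) -> np.ndarray:
    """Unit-step cell path over the first-to-last-match span of a column list."""
    matches = [idx for idx, (q, t) in enumerate(columns) if q is not None and t is not None]
    if not matches:
        return np.empty((0, 2), dtype=np.int64)
    span = columns[matches[0] : matches[-1] + 1]
    cells = []
    qi, tj = span[0]
    cells.append((qi, tj))
    for q, t in span[1:]:
        qi = q if q is not None else qi
        tj = t if t is not None else tj
        cells.append((qi, tj))
    return np.asarray(cells, dtype=np.int64)


def render_alignment(cells, query, target) -> tuple[str, str]:
    """Render a cell path as gapped strings.

    The first cell pairs its two residues; each following step emits a
    residue pair (diagonal), query residue over ``-`` (vertical), or
    ``-`` over target residue (horizontal).
    """
    qseq, tseq = query.sequence, target.sequence
    cells = np.asarray(cells, dtype=np.int64)
    if cells.size == 0:
        return "", ""
    if (
        cells[:, 0].min() < 0
        or cells[:, 1].min() < 0
        or cells[:, 0].max() >= len(qseq)
        or cells[:, 1].max() >= len(tseq)
    ):
        raise ValueError("alignment cells outside sequence bounds")
    steps = np.diff(cells, axis=0)
    if steps.size and (
        steps.min() < 0 or steps.max() > 1 or (steps.sum(axis=1) < 1).any()
    ):
        raise ValueError("alignment cells are not strictly monotone unit steps")
    gq = [qseq[cells[0, 0]]]
    gt = [tseq[cells[0, 1]]]
    for (i, j), (di, dj) in zip(cells[1:], steps):
        gq.append(qseq[i] if di else "-")
        gt.append(tseq[j] if dj else "-")
    return "".join(gq), "".join(gt)


def render_global(aln: GlobalAlignment, query, target) -> tuple[str, str]:
    """Gapped strings for a global alignment, covering both full sequences."""
    gq, gt = [], []
    for q, t in aln.columns:
        gq.append(query.sequence[q] if q is not None else "-")
        gt.append(target.sequence[t] if t is not None else "-")
    return "".join(gq), "".join(gt)
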