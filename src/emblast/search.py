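"""Database search: prefilter, per-pair alignment, ranking, reporting."""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from emblast.align_core import (
    DEFAULT_SIGMA_FACTOR,
    DEFAULT_WINDOW,
    GlobalAlignment,
    LocalAlignment,
    extract_local_alignments,
    filter_alignments,
    global_align,
    render_alignment,
    render_global,
    scoring_matrix,
    traceback_paths,
)
from emblast.embedding_store import EmbeddingDatabase, EmbeddingMatrix, SequenceRecord
from emblast.prefilter import (
    DEFAULT_PERCENTILE,
    DEFAULT_PREFILTER_STRIDE,
    DEFAULT_PREFILTER_WINDOW,
    PrefilterResult,
    chunk_embedding,
    prefilter_score,
    select_candidates,
)
from emblast.substitution import normalize_rows, substitution_matrix

__all__ = ["SearchParams", "SearchHit", "align_pair", "search", "write_report"]

REPORT_COLUMNS = [
    "query_id",
    "target_id",
    "mode",
    "score",
    "prefilter_score",
    "query_start",
    "query_end",
    "target_start",
    "target_end",
    "alignment_length",
    "gapped_query",
    "gapped_target",
]


@dataclass(frozen=True)
class SearchParams:
    """All tunables of a search run.

    The extraction threshold (``sigma_factor`` times the per-pair
    substitution-matrix standard deviation) is the real sensitivity
    control; ``min_score`` is only a reporting floor.
    """

    mode: str = "local"
    window: int = DEFAULT_WINDOW
    sigma_factor: float = DEFAULT_SIGMA_FACTOR
    prefilter_enabled: bool = True
    prefilter_window: int = DEFAULT_PREFILTER_WINDOW
    prefilter_stride: int = DEFAULT_PREFILTER_STRIDE
    prefilter_percentile: float = DEFAULT_PERCENTILE
    min_score: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("local", "global"):
            raise ValueError(f"mode must be 'local' or 'global', got {self.mode!r}")
        if min(self.window, self.prefilter_window, self.prefilter_stride) < 1:
            raise ValueError("windows and strides must be >= 1")
        if not 0.0 <= self.prefilter_percentile <= 100.0:
            raise ValueError("prefilter percentile must be in [0, 100]")


@dataclass
class SearchHit:
    """All alignments of one query/target pair, best first."""

    query_id: str
    target_id: str
    mode: str
    alignments: list
    best_score: float
    prefilter_score: float | None = None


def _align_local(S, params: SearchParams) -> list[LocalAlignment]:
    H = scoring_matrix(S)
    raw: list[LocalAlignment] = []
    for path in traceback_paths(H, S):
        raw.extend(
            extract_local_alignments(
                path, S.sigma, window=params.window, sigma_factor=params.sigma_factor
            )
        )
    return filter_alignments(raw)


def align_pair(
    query: EmbeddingMatrix,
    query_record: SequenceRecord,
    target: EmbeddingMatrix,
    target_record: SequenceRecord,
    params: SearchParams | None = None,
    prefilter_value: float | None = None,
) -> SearchHit:
    """Align one pair of sequences given their embeddings."""
    params = params or SearchParams()
    S = substitution_matrix(normalize_rows(query), normalize_rows(target))
    if params.mode == "global":
        aln = global_align(S)
        aln.gapped_query, aln.gapped_target = render_global(
            aln, query_record, target_record
        )
        alignments: list = [aln]
        best = aln.score
    else:
        alignments = _align_local(S, params)
        for aln in alignments:
            aln.gapped_query, aln.gapped_target = render_alignment(
                aln.cells, query_record, target_record
            )
        best = alignments[0].score if alignments else float("-inf")
    return SearchHit(
        query_id=query.id,
        target_id=target.id,
        mode=params.mode,
        alignments=alignments,
        best_score=best,
        prefilter_score=prefilter_value,
    )


def search(
    query: EmbeddingMatrix,
    query_record: SequenceRecord,
    db: EmbeddingDatabase,
    params: SearchParams | None = None,
) -> list[SearchHit]:
    """Search a query against an embedding database.

    With the prefilter enabled only entries at or above the configured
    percentile of windowed-cosine scores are fully aligned.  Hits with at
    least one alignment scoring >= min_score are returned sorted by
    descending best score, ties broken by target id.
    """
    params = params or SearchParams()
    if len(db) == 0:
        return []
    dim = db.embedding_dim
    if query.m != dim:
        raise ValueError(
            f"query embedding dimension {query.m} does not match database ({dim})"
        )

    pf_scores: dict[str, float] | None = None
    candidates = list(db)
    if params.prefilter_enabled:
        window = int(db.metadata.get("prefilter_window", params.prefilter_window))
        stride = int(db.metadata.get("prefilter_stride", params.prefilter_stride))
        # the query is chunked densely (stride 1) so that some query/target
        # window pair is register-aligned with any shared segment, whatever
        # its diagonal offset; the database side keeps the coarser build-time
        # stride, which is what bounds storage and scan cost
        qchunks = chunk_embedding(query, window=window, stride=1)
        pf_scores = {}
        for key in db:
            tchunks = db.chunks.get(key) or chunk_embedding(
                db[key][0], window=window, stride=stride
            )
            pf_scores[key] = prefilter_score(qchunks, tchunks)
        results = [PrefilterResult(k, v) for k, v in sorted(pf_scores.items())]
        candidates = sorted(select_candidates(results, params.prefilter_percentile))

    hits: list[SearchHit] = []
    for key in candidates:
        emb, rec = db[key]
        hit = align_pair(
            query,
            query_record,
            emb,
            rec,
            params,
            prefilter_value=pf_scores[key] if pf_scores else None,
        )
        if hit.alignments and hit.best_score >= params.min_score:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.best_score, h.target_id))
    return hits


def write_report(
    hits: Sequence[SearchHit], path: str | Path, params: SearchParams | None = None
) -> None:
    """Tab-separated hit report, one row per alignment.

    Coordinates are 1-based inclusive; a commented header records the
    tool version and the full parameter set for reproducibility.
    """
    from emblast import __version__

    out = io.StringIO()
    out.write(f"# emblast {__version__}\n")
    if params is not None:
        flags = " ".join(f"{k}={v}" for k, v in sorted(vars(params).items()))
        out.write(f"# params: {flags}\n")
    out.write("\t".join(REPORT_COLUMNS) + "\n")
    for hit in hits:
        for aln in hit.alignments:
            if isinstance(aln, GlobalAlignment):
                matches = aln.match_cells
                qs, qe = (matches[0][0], matches[-1][0]) if matches else (0, -1)
                ts, te = (matches[0][1], matches[-1][1]) if matches else (0, -1)
                length = len(aln.columns)
            else:
                qs, qe = aln.query_start, aln.query_end
                ts, te = aln.target_start, aln.target_end
                length = len(aln)
            row = [
                hit.query_id,
                hit.target_id,
                hit.mode,
                f"{aln.score:.6f}",
                "" if hit.prefilter_score is None else f"{hit.prefilter_score:.6f}",
                str(qs + 1),
                str(qe + 1),
                str(ts + 1),
                str(te + 1),
                str(length),
                aln.gapped_query,
                aln.gapped_target,
            ]
            out.write("\t".join(row) + "\n")
    Path(path).write_text(out.getvalue())
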