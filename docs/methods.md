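# Methods

## Model

emblast detects local and global similarity between two proteins by
comparing their per-residue embeddings directly, with no fixed
amino-acid substitution table.  Given embeddings `E_q` (n x m) and
`E_t` (k x m), every row is first scaled to unit Euclidean norm, and the
substitution matrix is the full cosine-similarity grid

    S = E_q_norm @ E_t_norm.T,       s_ij in [-1, 1].

Because embeddings are contextual, the same amino-acid pair can score
differently at different positions; similarity of unrelated regions
concentrates near zero, which is what lets the dynamic programming run
without gap penalties.

### Local mode

A cumulative score matrix `H` of size (n+1) x (k+1) is filled with a
zero first row and column and

    h[i][j] = max( h[i-1][j-1] + s[i-1][j-1],  h[i-1][j],  h[i][j-1] ).

Gap moves cost nothing and the matrix is not truncated at zero.  Note
that with zero borders this recurrence keeps `H` non-negative and
monotone non-decreasing in both indices; cells with cumulative score
zero occur exactly where no positive-scoring chain reaches.

Instead of tracing back from the single best cell, one candidate path is
started from every cell of the bottom row and rightmost column of `H`
(n + k - 1 distinct starts; the corner is shared).  Each walk moves to
the best of the three predecessor cells — ties prefer the diagonal, then
the vertical move, so substitutions win over gaps — and stops when the
cumulative score is no longer positive or an edge is reached.  Paths are
reversed into N-to-C order and exact duplicates are dropped.

Each path is then scanned on its substitution values (every cell of the
path carries its `s_ij`, including cells entered by gap moves).  A
centered moving average of window `w` (default 15 cells; windows are
clipped at path ends, and a path shorter than the window is judged on
its overall mean) is compared against the threshold

    threshold = sigma_factor * sigma,

where `sigma` is the population standard deviation of all elements of
this pair's substitution matrix and `sigma_factor` defaults to 2.
Maximal runs of positions at or above the threshold become local
alignments.  We deliberately report the run of qualifying *positions*
rather than the union of every qualifying window's footprint: the
footprint union pads each captured segment with up to `w - 1` background
cells per side, which measurably destroys per-residue precision, while
the centered-run reading trims to within a cell or two of the true
segment boundary.

An alignment's score is the arithmetic mean of its per-cell substitution
values — dimensionless and comparable across lengths.  Because many
border starts funnel into the same high-scoring region, a redundancy
pass keeps, among alignments sharing more than half of the smaller one's
cells, only the one with the largest *summed* substitution score
(mean x length).  Ranking this pass by the sum rather than the mean
matters: a one-cell fragment of a strong alignment has a higher mean
than the full alignment and would otherwise displace it.  The reported
score stays the mean.

### Global mode

Needleman–Wunsch with the similarity table replaced by `S` and the gap
penalty set to zero — the fill is the same recurrence as above, and the
traceback runs from the bottom-right corner to the origin (diagonal
preferred on ties), so every residue of both sequences appears in a
match or gap column.  The optimum equals the best strictly-increasing
chain of cells through `S` (gaps are free), which is what the exhaustive
test oracle enumerates.  The score is the mean substitution value over
match columns; `total_score` carries the sum (the DP optimum).

A zero-gap global alignment may in principle open with gap columns.  The
unit-step cell-path representation used for local alignments cannot
express a leading gap (its first cell always renders as a match), so
`GlobalAlignment` stores explicit alignment columns
`(query_index | None, target_index | None)` as the authoritative record
and derives the cell path for the first-to-last-match span.

### Prefilter

Scanning a database with full dynamic programming is quadratic per pair,
so candidates are screened first.  Each embedding is cut into windows of
30 residues (full embedding width), flattened and unit-normalized; the
prefilter score of a pair is the maximum cosine similarity over all
window pairs, so one strongly similar region suffices.  Database chunk
vectors are precomputed at build time with a stride of 15 (half the
window) and stored with the archive; the *query* is chunked densely
(stride 1) at search time.  Dense chunking on one side is essential, not
cosmetic: flattened windows compare row-by-row, so two windows that are
not register-aligned with a shared segment decorrelate completely, and
with a coarse stride on both sides a segment whose query-target offset
is not a multiple of the stride becomes invisible to the screen.  With
one dense side every offset is covered and a planted 40-residue segment
at signal 0.7 scores ≥ ~0.58 even in the worst register (25/30 window
overlap) against a decoy noise floor of about 2-3/sqrt(30 m).

Candidate selection keeps, per query, the entries scoring at or above a
percentile (nearest-rank, default 90th) of that query's score
distribution; ties at the cutoff are all kept.  An absolute-threshold
variant is also exposed.  The percentile is computed per query, not
globally across queries.

### Metrics

Alignments are reduced to sets of aligned residue-index pairs (gap
columns contribute nothing).  Against a reference set: precision is the
fraction of test pairs present in the reference, sensitivity the
fraction of reference pairs recovered, motif coverage the fraction of a
motif's pairs recovered.  A pair is correct only on exact index identity
(no shift tolerance).  When one query/target pair yields several local
alignments, the default pools their pairs ("union", conflicts resolved
in favor of the higher-scoring alignment to keep the set one-to-one); a
"best" mode uses only the top alignment.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 15 cells | moving-average window for local extraction; about half a short paired secondary-structure motif. Smaller = more fragmentary, noisier alignments |
| `sigma_factor` | 2 | capture threshold in multiples of the per-pair substitution-matrix standard deviation; larger is stricter |
| `prefilter_window` | 30 residues | chunk length for the cosine screen |
| `prefilter_stride` | 15 residues | database-side chunk stride (query side is dense) |
| `prefilter_percentile` | 90 | per-query nearest-rank cutoff on prefilter scores |
| `min_score` | 0 | reporting floor on alignment scores; the sigma threshold is the real sensitivity control |

`sigma` is taken as the population standard deviation over all
`n x k` elements of one pair's substitution matrix.  Per-row standard
deviations averaged, or a database-wide value, would be defensible
alternatives; the global element-wise value is the simplest and is used
everywhere the threshold is needed.

## Synthetic test substrate

Every stage downstream of row normalization sees only unit-norm row
vectors, so the generator produces exactly that: rows drawn isotropically
and normalized (dimension 64 by default; cosines between unrelated rows
then concentrate near 0 with spread 1/8).  Homology is planted by
copying a query segment into a fresh background with each copied row
mixed as `s*q + sqrt(1-s^2)*z_perp`, `z_perp` unit noise orthogonalized
against the copied row, so the within-segment cosine equals the
requested signal exactly and the homologous residue pairs are known by
construction.  Default study conditions for the bench: sequence length
150, segment length 40, signal 0.7, 50 decoys (lengths 100-200) plus 5
homologs per database, everything deterministic in one seed.

What this substrate does *not* emulate: the anisotropy of real
language-model embedding spaces, positional/terminal effects, repeats
and compositional bias, or correlations between adjacent residues.
Passing the planted-segment bench therefore demonstrates the alignment
machinery (recurrence, traceback, extraction, prefilter, ranking) is
correct under its stated noise model — not biological sensitivity, which
the original large-scale benchmarks address with real embeddings.  Real
ProtT5 substitution matrices of unrelated proteins have a standard
deviation around 0.075; the synthetic substrate's is about 1/sqrt(m)
(0.125 at m = 64), so absolute thresholds differ while everything
expressed in sigma units transfers.

## Numerical choices

- Embeddings are stored as float32 (matching half/single-precision model
  output); all alignment arithmetic is float64.
- Substitution values are clipped to [-1, 1] after the matrix product to
  absorb floating error before thresholding; row normalization rejects
  rows with norm below 1e-12.
- Traceback and global-alignment tie-breaks: diagonal, then vertical,
  then horizontal.  Global mode emits exactly one alignment (the first
  optimum under this order).
- The scoring recurrence considers only the three single-step
  predecessors, so fill and traceback are mutually consistent;
  unbounded vertical/horizontal back-jumps would change nothing anyway,
  because zero-cost single gap steps already compose to any longer jump
  with equal score.
- The DP fill and the traceback walk are numba-JIT-compiled; results are
  identical to the pure-Python reference implementations used as test
  oracles to 1e-9.
- Empty-path, empty-database, and shorter-than-window inputs are handled
  explicitly; degenerate zero-norm embeddings raise with the offending
  row index.

## Known limitations

- No E-values or score statistics: scores are mean cosines, comparable
  across alignments but not calibrated probabilities.
- The alignment-count (as opposed to aligned-cell-count) response to the
  sigma threshold is not monotone: a stricter threshold can split one
  captured run into two shorter ones.  Aligned-cell counts are monotone
  and are what the test-bench asserts.
- Sequences are amino acids only (20 letters + X); B/Z/U/O are rejected
  rather than silently substituted.  No hard length limit is imposed.
- The external ProtT5 backend is optional and untested offline; it is
  isolated behind the backend interface so the entire suite runs without
  any model download.
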