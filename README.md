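# emblast

Detection of remote protein homology by directly comparing per-residue
embeddings from a protein language model, without substitution tables or
sequence profiles.

## The problem and the method

Classical sequence search scores residue pairs with a fixed substitution
matrix, which loses signal once sequence identity drops into the
twilight zone. Protein language models map each residue to a contextual
embedding vector in which structurally and functionally equivalent
positions stay close even when the letters have diverged. `emblast`
turns that observation into an alignment algorithm:

1. **Substitution matrix.** For a query with embeddings
   `E_q ∈ R^{n×m}` and a target with `E_t ∈ R^{k×m}`, normalize each
   row to unit length and form the dense cosine-similarity matrix

   ```
   S = Ê_q · Ê_tᵀ ,   S_ij ∈ [-1, 1]
   ```

   Its population standard deviation `σ = std(S)` sets the
   signal-versus-background scale for that pair.

2. **Cumulative scoring.** A gapless variant of local alignment fills
   `H ∈ R^{(n+1)×(k+1)}` with zero borders and

   ```
   H_ij = max( H_{i-1,j-1} + S_{i-1,j-1},  H_{i-1,j},  H_{i,j-1} )
   ```

   so scores accumulate along paths without ever being truncated.

3. **Multi-start traceback.** A path is traced from every cell on the
   bottom row and right column (`n + k − 1` starts), always moving to
   the best predecessor and preferring the diagonal on ties.

4. **Local-alignment extraction.** Each path's per-cell similarity
   profile is smoothed with a centered moving average (window 15) and
   maximal runs above `2σ` become candidate alignments; overlapping
   redundant candidates are removed and survivors are ranked by their
   mean per-residue similarity.

5. **Prefilter.** For large databases, flattened embedding windows
   (30 residues, stride 15 on the database side) are compared by
   cosine similarity, and only targets scoring in the top decile are
   aligned in full. The prefilter only removes candidates — alignments
   of surviving targets are bit-identical to an unfiltered run.

A global mode (Needleman–Wunsch with zero gap penalty over the same
`S`) is available for end-to-end comparisons.

A full scientific description, including every deliberate deviation and
its rationale, is in [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic benchmark — 10 random decoys plus 2 targets that
carry a 40-residue segment correlated (cosine 0.7) with a region of the
query — then index and search it:

```console
$ emblast synth demo --n-decoys 10 --n-homologs 2 --seed 7
INFO synthetic benchmark: 10 decoys + 2 homologs -> demo
$ emblast makedb demo/db
INFO indexed 12 entries (window 30, stride 15)
$ emblast search demo/query demo/db demo/hits.tsv
INFO query query: 2 of 12 entries hit
INFO wrote demo/hits.tsv
$ head -5 demo/hits.tsv | cut -f1-10
# emblast 0.1.0
# params: min_score=0.0 mode=local prefilter_enabled=True prefilter_percentile=90.0 prefilter_stride=15 prefilter_window=30 sigma_factor=2.0 window=15
query_id  target_id    mode   score     prefilter_score  query_start  query_end  target_start  target_end  alignment_length
query     homolog_000  local  0.625830  0.700000         76           116        98            142         45
query     homolog_001  local  0.620277  0.700000         90           134        23            64          46
```

Both planted homologs are found (none of the 10 decoys produce a hit),
and the reported 1-based coordinates land on the planted regions. The
per-residue agreement with the generator's ground truth
(`demo/ground_truth.tsv`) can be scored directly:

```console
$ emblast eval test_pairs.tsv ref_pairs.tsv
precision	0.9512
sensitivity	0.9750
```

The same pipeline is available as a Python API:

```python
from emblast import SearchParams, align_pair, make_planted_pair

q, q_rec, t, t_rec, spec = make_planted_pair(seed=7)
hit = align_pair(q, q_rec, t, t_rec, SearchParams())
best = hit.alignments[0]
print(best.score, best.query_start, best.query_end)
```

## Scope

The synthetic backend produces isotropic unit-norm embeddings whose
background similarity scale (`σ ≈ 1/√m`) differs from real
protein-language-model embeddings; see docs/methods.md for what does
and does not transfer. Statistical significance estimates (E-values)
are not implemented.
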