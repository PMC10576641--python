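import numpy as np
import pytest

from emblast.align_core import (
    extract_local_alignments,
    filter_alignments,
    global_align,
    render_alignment,
    scoring_matrix,
    traceback_paths,
    AlignmentPath,
)
from emblast.embedding_store import SequenceRecord
from emblast.substitution import normalize_rows, substitution_matrix
from emblast.synth import random_embedding
from tests.helpers import (
    best_increasing_chain,
    enumerate_capture_runs,
    matrix_as_substitution,
    naive_scoring_fill,
)


class TestScoringMatrix:
    def test_zero_substitution_gives_zero_matrix(self):
        H = scoring_matrix(matrix_as_substitution(np.zeros((2, 2))))
        assert np.array_equal(H.values, np.zeros((3, 3)))

    def test_single_cell(self):
        H = scoring_matrix(matrix_as_substitution([[1.0]]))
        assert np.allclose(H.values, [[0, 0], [0, 1.0]])

    def test_two_by_two_diagonal(self):
        H = scoring_matrix(matrix_as_substitution([[0.9, -0.5], [-0.5, 0.9]]))
        assert H.values[2, 2] == pytest.approx(1.8, abs=1e-12)
        assert np.allclose(H.values, naive_scoring_fill(np.array([[0.9, -0.5], [-0.5, 0.9]])))

    def test_first_row_and_column_zero(self, rng):
        S = matrix_as_substitution(rng.uniform(-1, 1, size=(8, 5)))
        H = scoring_matrix(S)
        assert np.all(H.values[0] == 0) and np.all(H.values[:, 0] == 0)

    def test_matches_naive_reference_on_random_matrices(self, rng):
        for _ in range(25):
            n, k = rng.integers(1, 21, size=2)
            S = rng.uniform(-1, 1, size=(n, k))
            H = scoring_matrix(matrix_as_substitution(S))
            assert np.allclose(H.values, naive_scoring_fill(S), atol=1e-9)


class TestTraceback:
    def test_all_nonpositive_yields_no_paths(self):
        S = matrix_as_substitution(-np.ones((4, 6)))
        H = scoring_matrix(S)
        assert traceback_paths(H, S) == []

    def test_strong_diagonal_recovered_from_corner_start(self):
        S = matrix_as_substitution(np.full((3, 3), -0.5) + np.eye(3) * 1.4)
        H = scoring_matrix(S)
        paths = traceback_paths(H, S)
        diagonal = [p for p in paths if np.array_equal(p.cells, [[0, 0], [1, 1], [2, 2]])]
        assert diagonal, "no path follows the full diagonal"
        assert np.allclose(diagonal[0].per_cell_scores, 0.9)

    def test_start_count_bound(self, rng):
        # |L| + |K| - 1 border starts (corner shared) bounds the path count
        S = matrix_as_substitution(rng.uniform(-1, 1, size=(4, 6)))
        H = scoring_matrix(S)
        assert len(traceback_paths(H, S)) <= 4 + 6 - 1

    def test_paths_strictly_monotone_unit_steps(self, rng):
        for _ in range(10):
            n, k = rng.integers(2, 15, size=2)
            S = matrix_as_substitution(rng.uniform(-1, 1, size=(n, k)))
            for path in traceback_paths(scoring_matrix(S), S):
                steps = np.diff(path.cells, axis=0)
                if steps.size:
                    assert steps.min() >= 0 and steps.max() <= 1
                    assert (steps.sum(axis=1) >= 1).all()
                assert len(path.per_cell_scores) == len(path)

    def test_path_cells_carry_substitution_values(self, rng):
        S = matrix_as_substitution(rng.uniform(-1, 1, size=(6, 7)))
        for path in traceback_paths(scoring_matrix(S), S):
            expected = S.values[path.cells[:, 0], path.cells[:, 1]]
            assert np.allclose(path.per_cell_scores, expected)


class TestExtraction:
    def _path(self, scores):
        scores = np.asarray(scores, dtype=np.float64)
        cells = np.stack([np.arange(len(scores))] * 2, axis=1)
        return AlignmentPath(cells=cells, per_cell_scores=scores)

    def test_uniform_signal_spans_whole_path(self):
        alns = extract_local_alignments(
            self._path([0.9] * 30), sigma=0.075, window=3, sigma_factor=2.0
        )
        assert len(alns) == 1
        assert len(alns[0]) == 30
        assert alns[0].score == pytest.approx(0.9)

    def test_below_threshold_yields_nothing(self):
        alns = extract_local_alignments(
            self._path([0.05] * 30), sigma=0.075, window=3, sigma_factor=2.0
        )
        assert alns == []

    def test_two_blocks_match_window_enumeration_oracle(self):
        scores = [0.9] * 10 + [0.0] * 10 + [0.9] * 10
        alns = extract_local_alignments(
            self._path(scores), sigma=0.075, window=5, sigma_factor=2.0
        )
        expected = enumerate_capture_runs(np.asarray(scores), window=5, threshold=0.15)
        got = [(a.query_start, a.query_end) for a in alns]
        assert got == expected
        assert len(expected) == 2

    def test_random_paths_match_window_enumeration_oracle(self, rng):
        for _ in range(20):
            scores = rng.normal(0, 0.2, size=int(rng.integers(5, 60)))
            window = int(rng.integers(1, 12))
            alns = extract_local_alignments(
                self._path(scores), sigma=0.1, window=window, sigma_factor=1.5
            )
            expected = enumerate_capture_runs(scores, window=window, threshold=0.15)
            assert [(a.query_start, a.query_end) for a in alns] == expected

    def test_short_path_judged_on_overall_mean(self):
        alns = extract_local_alignments(
            self._path([0.5, 0.5]), sigma=0.1, window=10, sigma_factor=2.0
        )
        assert len(alns) == 1 and len(alns[0]) == 2
        assert extract_local_alignments(
            self._path([0.1, 0.1]), sigma=0.1, window=10, sigma_factor=2.0
        ) == []

    def test_score_is_mean_of_per_cell_values(self):
        scores = [0.4, 0.6, 0.8]
        alns = extract_local_alignments(
            self._path(scores), sigma=0.05, window=3, sigma_factor=2.0
        )
        assert alns[0].score == pytest.approx(np.mean(scores), abs=1e-9)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            extract_local_alignments(self._path([0.5]), sigma=0.1, window=0)

    def test_threshold_monotonicity_in_aligned_cells(self, rng):
        scores = rng.normal(0.15, 0.2, size=80)
        path = self._path(scores)
        counts = []
        for factor in [1.0, 1.5, 2.0, 2.5, 3.0]:
            alns = extract_local_alignments(path, sigma=0.1, window=15, sigma_factor=factor)
            counts.append(sum(len(a) for a in alns))
        assert counts == sorted(counts, reverse=True)


class TestFilterAlignments:
    def test_fragment_does_not_displace_containing_alignment(self):
        path = AlignmentPath(
            cells=np.stack([np.arange(20)] * 2, axis=1),
            per_cell_scores=np.full(20, 0.6),
        )
        long = extract_local_alignments(path, sigma=0.1, window=5)[0]
        frag = extract_local_alignments(
            AlignmentPath(cells=path.cells[:1], per_cell_scores=np.array([0.9])),
            sigma=0.1,
            window=5,
        )[0]
        kept = filter_alignments([frag, long])
        assert len(kept) == 1 and len(kept[0]) == 20

    def test_disjoint_alignments_all_kept_sorted_by_score(self):
        def aln(start, score, length=10):
            cells = np.stack([np.arange(start, start + length)] * 2, axis=1)
            return extract_local_alignments(
                AlignmentPath(cells=cells, per_cell_scores=np.full(length, score)),
                sigma=0.01,
                window=3,
            )[0]

        kept = filter_alignments([aln(0, 0.5), aln(100, 0.8)])
        assert [a.score for a in kept] == pytest.approx([0.8, 0.5])


class TestGlobalAlign:
    def test_single_cell(self):
        aln = global_align(matrix_as_substitution([[0.7]]))
        assert aln.columns == [(0, 0)]
        assert aln.score == pytest.approx(0.7)

    def test_self_alignment_is_pure_diagonal(self):
        E = normalize_rows(random_embedding(12, 16, seed=3))
        aln = global_align(substitution_matrix(E, E))
        assert aln.score == pytest.approx(1.0, abs=1e-6)
        assert aln.columns == [(i, i) for i in range(12)]

    def test_total_score_matches_exhaustive_enumeration(self, rng):
        for n in range(1, 6):
            for k in range(1, 7):
                for _ in range(5):
                    S = rng.uniform(-1, 1, size=(n, k))
                    aln = global_align(matrix_as_substitution(S))
                    assert aln.total_score == pytest.approx(
                        best_increasing_chain(S), abs=1e-9
                    )

    def test_columns_cover_both_sequences(self, rng):
        n, k = 5, 9
        aln = global_align(matrix_as_substitution(rng.uniform(-1, 1, size=(n, k))))
        qs = [q for q, _ in aln.columns if q is not None]
        ts = [t for _, t in aln.columns if t is not None]
        assert qs == list(range(n)) and ts == list(range(k))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            global_align(matrix_as_substitution(np.zeros((0, 3))))


class TestRenderAlignment:
    q = SequenceRecord("q", "MKV")
    t = SequenceRecord("t", "MR")

    def test_all_diagonal(self):
        assert render_alignment([(0, 0), (1, 1)], self.q, self.t) == ("MK", "MR")

    def test_vertical_step_gaps_target(self):
        assert render_alignment([(0, 0), (1, 0), (2, 1)], self.q, self.t) == ("MKV", "M-R")

    def test_horizontal_step_gaps_query(self):
        q = SequenceRecord("q", "M")
        assert render_alignment([(0, 0), (0, 1)], q, self.t) == ("M-", "MR")

    def test_non_monotone_cells_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            render_alignment([(1, 1), (0, 0)], self.q, self.t)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            render_alignment([(0, 0), (1, 5)], self.q, self.t)
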