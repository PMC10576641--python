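"""Shared test utilities and independent reference oracles.

Every oracle here is written naively (double loops, exhaustive
enumeration) and stays independent of the implementation path it
checks.
"""

import numpy as np

from emblast.embedding_store import EmbeddingMatrix
from emblast.substitution import SubstitutionMatrix


def embedding_from(values, id="custom"):
    return EmbeddingMatrix(id=id, values=np.asarray(values, dtype=np.float64))


def matrix_as_substitution(values):
    """Wrap an arbitrary value grid as a SubstitutionMatrix for DP tests."""
    values = np.asarray(values, dtype=np.float64)
    sigma = float(values.std()) if values.size else 0.0
    return SubstitutionMatrix(values=values, sigma=sigma)


def brute_force_cosine(a, b):
    """cosine(u, v) for every residue pair, cell by cell."""
    out = np.empty((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            u, v = a[i], b[j]
            out[i, j] = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return out


def naive_scoring_fill(S):
    """Cell-by-cell reference of the cumulative score recurrence."""
    n, k = S.shape
    H = np.zeros((n + 1, k + 1))
    for i in range(1, n + 1):
        for j in range(1, k + 1):
            H[i, j] = max(H[i - 1, j - 1] + S[i - 1, j - 1], H[i - 1, j], H[i, j - 1])
    return H


def best_increasing_chain(S):
    """Exhaustive optimum of a zero-gap global alignment.

    With free gaps the optimal global alignment score equals the best sum
    over chains of cells strictly increasing in both coordinates (the
    empty chain scores 0).  Enumerates every chain recursively.
    """
    n, k = S.shape

    def extend(i, j):
        best = 0.0
        for ii in range(i, n):
            for jj in range(j, k):
                cand = S[ii, jj] + extend(ii + 1, jj + 1)
                if cand > best:
                    best = cand
        return best

    return extend(0, 0)


def enumerate_capture_runs(scores, window, threshold):
    """Independent oracle for moving-average capture on one path.

    Evaluates the centered moving average (window clipped at the ends) at
    every position by direct slicing and returns the maximal runs of
    qualifying positions as (start, end) inclusive index pairs.
    """
    L = len(scores)
    if L < window:
        return [(0, L - 1)] if np.mean(scores) >= threshold else []
    half_lo = window // 2
    half_hi = (window - 1) // 2
    qualifying = []
    for p in range(L):
        lo = max(0, p - half_lo)
        hi = min(L, p + half_hi + 1)
        qualifying.append(np.mean(scores[lo:hi]) >= threshold)
    runs = []
    p = 0
    while p < L:
        if qualifying[p]:
            start = p
            while p + 1 < L and qualifying[p + 1]:
                p += 1
            runs.append((start, p))
        p += 1
    return runs
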