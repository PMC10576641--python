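"""Per-residue alignment-quality metrics against a reference alignment.

A reference (typically a structure-based alignment) and a test alignment
are reduced to sets of aligned residue-index pairs; precision is the
fraction of test pairs present in the reference, sensitivity the
fraction of reference pairs recovered, and motif coverage the fraction
of a designated motif's pairs recovered.  A correctly aligned pair means
exact index identity -- no shift tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from emblast.align_core import GlobalAlignment, LocalAlignment

__all__ = [
    "ResiduePairSet",
    "pairs_from_alignment",
    "pairs_from_alignments",
    "precision_sensitivity",
    "motif_coverage",
    "pairs_from_gapped",
    "read_pair_list",
]


@dataclass(frozen=True)
class ResiduePairSet:
    """One-to-one set of aligned (query_index, target_index) pairs, 0-based."""

    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        q = [p[0] for p in self.pairs]
        t = [p[1] for p in self.pairs]
        if len(set(q)) != len(q) or len(set(t)) != len(t):
            raise ValueError("residue pair set is not a one-to-one matching")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "ResiduePairSet":
        return cls(pairs=frozenset((int(a), int(b)) for a, b in pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def _match_pairs_from_cells(cells: np.ndarray) -> list[tuple[int, int]]:
    """Diagonal steps of a unit-step cell path; the first cell is a match."""
    cells = np.asarray(cells)
    if cells.size == 0:
        return []
    pairs = [(int(cells[0, 0]), int(cells[0, 1]))]
    steps = np.diff(cells, axis=0)
    for (i, j), (di, dj) in zip(cells[1:], steps):
        if di == 1 and dj == 1:
            pairs.append((int(i), int(j)))
    return pairs


def pairs_from_alignment(aln: LocalAlignment | GlobalAlignment) -> ResiduePairSet:
    """Aligned residue pairs of one alignment (gap columns contribute nothing)."""
    if isinstance(aln, GlobalAlignment):
        return ResiduePairSet.from_pairs(aln.match_cells)
    return ResiduePairSet.from_pairs(_match_pairs_from_cells(aln.cells))


def pairs_from_alignments(
    alignments: Sequence[LocalAlignment | GlobalAlignment],
    combine: str = "union",
) -> ResiduePairSet:
    """Pairs of several local alignments of one sequence pair.

    ``combine='union'`` pools every reported alignment (pairs seen with
    more than one partner keep the one from the higher-scoring
    alignment); ``combine='best'`` uses only the top-scoring alignment.
    """
    if combine not in ("union", "best"):
        raise ValueError(f"combine must be 'union' or 'best', got {combine!r}")
    if not alignments:
        return ResiduePairSet()
    ordered = sorted(alignments, key=lambda a: -a.score)
    if combine == "best":
        return pairs_from_alignment(ordered[0])
    taken_q: set[int] = set()
    taken_t: set[int] = set()
    pooled: list[tuple[int, int]] = []
    for aln in ordered:
        for q, t in pairs_from_alignment(aln).pairs:
            if q not in taken_q and t not in taken_t:
                pooled.append((q, t))
                taken_q.add(q)
                taken_t.add(t)
    return ResiduePairSet.from_pairs(pooled)


def precision_sensitivity(
    test: ResiduePairSet, reference: ResiduePairSet
) -> tuple[float, float]:
    """Fraction of test pairs that are correct, and of reference pairs found.

    An empty test set scores (0, 0) by convention; an empty reference is
    an error because sensitivity would be undefined.
    """
    if len(reference) == 0:
        raise ValueError("reference pair set is empty; sensitivity undefined")
    if len(test) == 0:
        return 0.0, 0.0
    correct = len(test.pairs & reference.pairs)
    return correct / len(test), correct / len(reference)


def motif_coverage(test: ResiduePairSet, motif: ResiduePairSet) -> float:
    """Fraction of the motif's residue pairs recovered by the test alignment."""
    if len(motif) == 0:
        raise ValueError("motif pair set is empty; coverage undefined")
    return len(test.pairs & motif.pairs) / len(motif)


def pairs_from_gapped(gapped_query: str, gapped_target: str) -> ResiduePairSet:
    """Aligned pairs of a two-row gapped alignment ('-' marks a gap)."""
    if len(gapped_query) != len(gapped_target):
        raise ValueError("gapped rows differ in length")
    qi = ti = 0
    pairs = []
    for a, b in zip(gapped_query, gapped_target):
        if a != "-" and b != "-":
            pairs.append((qi, ti))
        if a != "-":
            qi += 1
        if b != "-":
            ti += 1
    return ResiduePairSet.from_pairs(pairs)


def read_pair_list(path: str | Path) -> ResiduePairSet:
    """Read a tab-separated (query_index, target_index) pair list."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        pairs.append((int(a), int(b)))
    return ResiduePairSet.from_pairs(pairs)
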