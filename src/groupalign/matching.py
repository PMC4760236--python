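"""One-to-one feature matching on the bipartite score graph.

Production path: a greedy approximation — repeatedly pick the heaviest
remaining edge, add it to the matching and discard all edges sharing an
endpoint — which guarantees at least half the optimal total weight and
runs in O(m log n), dominated by one sort of the edge list. An exact
maximum-weight matcher (the assignment-problem route) is provided for
small instances and for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ParameterError, ValidationError
from .peaks import Matching, PeakList
from .similarity import ScoreMatrix


@dataclass(frozen=True)
class BipartiteInstance:
    """Edges (i, j, weight>0) between run-A indices [0, n_a) and run-B indices [0, n_b)."""

    edges: Tuple[Tuple[int, int, float], ...]
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", tuple((int(i), int(j), float(w)) for i, j, w in self.edges)
        )
        for i, j, w in self.edges:
            if not (0 <= i < self.n_a and 0 <= j < self.n_b):
                raise ValidationError(f"edge ({i}, {j}) out of range for ({self.n_a}, {self.n_b})")
            if not w > 0:
                raise ValidationError(f"edge ({i}, {j}) has non-positive weight {w}")

    @classmethod
    def from_score_matrix(cls, S: ScoreMatrix, include_zero: bool = False) -> "BipartiteInstance":
        """Build the graph from stored scores.

        Zero-weight entries (the worst in-window pair) are dropped by
        default: matching on zero evidence would only inflate false
        positives. ``include_zero`` keeps them with a tiny positive weight
        so they remain eligible.
        """
        edges = []
        for i, j, v in S.entries():
            if v > 0:
                edges.append((i, j, v))
            elif include_zero:
                edges.append((i, j, 1e-12))
        return cls(tuple(edges), S.shape[0], S.shape[1])


@dataclass(frozen=True)
class IndexMatching:
    """A matching over indices, with its total weight."""

    pairs: Tuple[Tuple[int, int], ...]
    total_weight: float

    def to_matching(self, run_a: PeakList, run_b: PeakList, S: ScoreMatrix) -> Matching:
        lookup = S.to_dict()
        return Matching(
            (run_a[i].id, run_b[j].id, lookup.get((i, j), 0.0)) for i, j in self.pairs
        )


def greedy_match(instance: BipartiteInstance) -> IndexMatching:
    """Greedy half-approximate maximum-weight bipartite matching.

    Edges are taken in non-increasing weight order, ties broken by
    ascending (i, j); an edge is kept iff both endpoints are still free.
    The result is maximal and deterministic, and its total weight is at
    least half the maximum.
    """
    ordered = sorted(instance.edges, key=lambda e: (-e[2], e[0], e[1]))
    used_a = [False] * instance.n_a
    used_b = [False] * instance.n_b
    pairs: List[Tuple[int, int]] = []
    total = 0.0
    for i, j, w in ordered:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            pairs.append((i, j))
            total += w
    return IndexMatching(tuple(sorted(pairs)), total)


def exact_match(instance: BipartiteInstance, max_size: int = 2000) -> IndexMatching:
    """Exact maximum-weight bipartite matching via the assignment problem.

    Weights are laid out densely (absent edges weigh 0) and a maximizing
    assignment computed; assigned pairs without a positive edge are
    discarded, which is optimal because all edge weights are positive.
    Gated to instances below ``max_size`` per side.
    """
    if instance.n_a > max_size or instance.n_b > max_size:
        raise ParameterError(
            f"exact matching gated to instances <= {max_size} per side, "
            f"got ({instance.n_a}, {instance.n_b})"
        )
    if not instance.edges:
        return IndexMatching((), 0.0)
    dense = np.zeros((instance.n_a, instance.n_b))
    for i, j, w in instance.edges:
        dense[i, j] = w
    row_ind, col_ind = linear_sum_assignment(dense, maximize=True)
    pairs = [(int(i), int(j)) for i, j in zip(row_ind, col_ind) if dense[i, j] > 0]
    total = float(sum(dense[i, j] for i, j in pairs))
    return IndexMatching(tuple(sorted(pairs)), total)
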