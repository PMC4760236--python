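"""Blending raw similarities with cluster similarity: S = alpha*W + (1-alpha)*L.

The cluster similarity matrix L = C_A · W · C_B accumulates, for a pair
(i, j), the similarity mass flowing between i's related-peak group in run A
and j's related-peak group in run B — pairs whose groups mutually support
each other are upweighted, isolated pairs are downweighted (because
alpha <= 1). Since L sums weights it can exceed 1 on large groups, so it is
rescaled by its maximum entry (toggleable) before blending, restoring a
common [0, 1] scale with W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import DimensionError, ParameterError
from .grouping import MembershipMatrix
from .similarity import ScoreMatrix


@dataclass(frozen=True)
class BlendWeight:
    """The blending parameter alpha in [0, 1]; alpha=1 uses W only, 0 uses L only."""

    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0) or not math.isfinite(self.alpha):
            raise ParameterError(f"alpha must lie in [0, 1], got {self.alpha}")


def cluster_similarity(W: ScoreMatrix, c_a: MembershipMatrix, c_b: MembershipMatrix) -> ScoreMatrix:
    """Compute L = C_A · W · C_B as a sparse score matrix (role L).

    L_ij sums W weight from peaks grouped with i in run A to peaks grouped
    with j in run B; only nonzero products are stored.
    """
    n_a, n_b = W.shape
    if c_a.n != n_a or c_b.n != n_b:
        raise DimensionError(
            f"membership shapes ({c_a.n}, {c_b.n}) do not conform with W shape {W.shape}"
        )
    w_csr = W.to_csr()
    ca = sparse.csr_matrix(c_a.matrix)
    cb = sparse.csr_matrix(c_b.matrix)
    L = (ca @ w_csr @ cb).tocoo()
    mask = L.data != 0
    return ScoreMatrix(W.shape, L.row[mask], L.col[mask], L.data[mask], role="L")


def combine(W: ScoreMatrix, L: ScoreMatrix, blend: BlendWeight, normalize_L: bool = True) -> ScoreMatrix:
    """Blend W and L into the final score matrix S (role S).

    S = alpha*W + (1-alpha)*L-hat entrywise, where L-hat is L rescaled by
    its maximum entry (identity when the maximum is 0 or ``normalize_L`` is
    off). Scores are kept only for pairs holding a W entry: the m/z and RT
    windows are hard thresholds, so L cannot create matches outside them.
    """
    if W.shape != L.shape:
        raise DimensionError(f"W shape {W.shape} != L shape {L.shape}")
    alpha = blend.alpha
    l_scale = L.max_value()
    scale = l_scale if (normalize_L and l_scale > 0) else 1.0
    l_lookup = L.to_dict()
    values = [
        alpha * w + (1.0 - alpha) * (l_lookup.get((i, j), 0.0) / scale)
        for i, j, w in W.entries()
    ]
    return ScoreMatrix(W.shape, W.rows.copy(), W.cols.copy(), values, role="S")
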