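"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: matchings are found by
exhaustive enumeration, and mixture-model co-membership posteriors by
summing over every set partition with closed-form marginal likelihoods.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import multivariate_normal


def brute_force_best_matching(dense: np.ndarray) -> Tuple[float, Tuple[Tuple[int, int], ...]]:
    """Maximum-weight matching by enumerating all row→column assignments.

    Rows may stay unassigned; zero entries mean "no edge". Exponential —
    use only on tiny instances.
    """
    n_a, n_b = dense.shape
    best_total = 0.0
    best_pairs: Tuple[Tuple[int, int], ...] = ()

    def recurse(row: int, used_cols: int, total: float, pairs: List[Tuple[int, int]]) -> None:
        nonlocal best_total, best_pairs
        if row == n_a:
            if total > best_total:
                best_total, best_pairs = total, tuple(pairs)
            return
        recurse(row + 1, used_cols, total, pairs)  # leave row unmatched
        for col in range(n_b):
            if dense[row, col] > 0 and not (used_cols >> col) & 1:
                pairs.append((row, col))
                recurse(row + 1, used_cols | (1 << col), total + dense[row, col], pairs)
                pairs.pop()

    recurse(0, 0, 0.0, [])
    return best_total, best_pairs


def set_partitions(items: Sequence[int]):
    """All set partitions of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield [[first]] + part


def dp_partition_posterior(
    rts: Sequence[float],
    concentration: float,
    cluster_sd: float,
    prior_sd: float,
    prior_mean: Optional[float] = None,
) -> np.ndarray:
    """Exact DP-mixture co-membership posterior by exhaustive enumeration.

    The weight of a partition is the CRP prior, concentration^K *
    prod (n_k - 1)!, times the marginal likelihood of each cluster's data
    under a Gaussian with unknown mean ~ N(prior_mean, prior_sd^2) and
    known observation sd ``cluster_sd`` — i.e. a multivariate normal with
    covariance cluster_sd^2 I + prior_sd^2 J.
    """
    t = np.asarray(rts, dtype=float)
    n = len(t)
    mu0 = float(t.mean()) if prior_mean is None else prior_mean
    parts = list(set_partitions(range(n)))
    log_weights = []
    for part in parts:
        lw = len(part) * math.log(concentration)
        for block in part:
            lw += math.lgamma(len(block))
            x = t[list(block)]
            m = len(block)
            cov = cluster_sd**2 * np.eye(m) + prior_sd**2 * np.ones((m, m))
            lw += multivariate_normal.logpdf(x, mean=np.full(m, mu0), cov=cov)
        log_weights.append(lw)
    log_weights = np.asarray(log_weights)
    weights = np.exp(log_weights - log_weights.max())
    weights /= weights.sum()

    co = np.zeros((n, n))
    for part, w in zip(parts, weights):
        for block in part:
            for i in block:
                for j in block:
                    if i != j:
                        co[i, j] += w
    return co


def adjusted_rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Adjusted Rand index between two hard partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    classes_a, ia = np.unique(a, return_inverse=True)
    classes_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(classes_a), len(classes_b)), dtype=np.int64)
    for x, y in zip(ia, ib):
        table[x, y] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n) if n > 1 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def random_bipartite_dense(rng: np.random.Generator, max_side: int = 8, density: float = 0.7) -> np.ndarray:
    """A random weighted bipartite instance as a dense matrix (0 = no edge)."""
    n_a = int(rng.integers(1, max_side + 1))
    n_b = int(rng.integers(1, max_side + 1))
    dense = rng.uniform(0.01, 1.0, size=(n_a, n_b))
    dense[rng.random((n_a, n_b)) > density] = 0.0
    return dense
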