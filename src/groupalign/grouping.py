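"""Related-peak grouping within a single run.

Peaks produced by the same compound — isotopologues, adducts, fragments —
coelute and therefore cluster in retention time. Two grouping strategies
produce a square per-run co-membership matrix C (zero diagonal):

* **greedy**: seed at the most intense unclustered peak, absorb all
  unclustered peaks within an RT window g_tol (optionally filtered by the
  Pearson correlation of chromatographic shape traces), repeat. Binary C.
* **mixture**: a Dirichlet-process Gaussian mixture on RT, sampled with
  collapsed Gibbs; C_ij is the fraction of kept samples in which peaks
  i and j share a cluster. Probabilistic C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DimensionError, ParameterError
from .peaks import PeakList, ShapeTrace


class MembershipMatrix:
    """Square co-membership matrix for one run: symmetric, zero diagonal.

    Entries lie in [0, 1]: binary for a hard partition (greedy grouping),
    posterior co-assignment probabilities for the mixture model. ``labels``
    holds the hard cluster labels when the matrix encodes a partition.
    """

    def __init__(self, matrix: np.ndarray, mode: str, labels: Optional[np.ndarray] = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise DimensionError(f"membership matrix must be square, got {matrix.shape}")
        if not np.allclose(matrix, matrix.T):
            raise DimensionError("membership matrix must be symmetric")
        if matrix.size and (matrix.min() < 0 or matrix.max() > 1):
            raise DimensionError("membership entries must lie in [0, 1]")
        np.fill_diagonal(matrix, 0.0)
        self.matrix = matrix
        self.mode = mode  # "binary" | "probabilistic"
        self.labels = None if labels is None else np.asarray(labels, dtype=np.intp)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "MembershipMatrix":
        labels = np.asarray(labels, dtype=np.intp)
        same = (labels[:, None] == labels[None, :]).astype(float)
        return cls(same, mode="binary", labels=labels)

    @classmethod
    def zeros(cls, n: int) -> "MembershipMatrix":
        return cls(np.zeros((n, n)), mode="binary", labels=np.arange(n))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MembershipMatrix):
            return NotImplemented
        return self.mode == other.mode and np.array_equal(self.matrix, other.matrix)

    def __repr__(self) -> str:
        return f"MembershipMatrix(n={self.n}, mode={self.mode!r})"


@dataclass(frozen=True)
class GreedyGroupingParams:
    """RT window g_tol (seconds) and optional Pearson shape threshold c."""

    g_tol: float
    corr_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.g_tol > 0 and math.isfinite(self.g_tol)):
            raise ParameterError(f"g_tol must be positive, got {self.g_tol}")
        if self.corr_threshold is not None and not (-1.0 <= self.corr_threshold <= 1.0):
            raise ParameterError(
                f"corr_threshold must lie in [-1, 1], got {self.corr_threshold}"
            )


@dataclass(frozen=True)
class MixtureParams:
    """Hyperparameters of the DP Gaussian mixture on RT.

    ``concentration`` is the Dirichlet-process concentration; ``cluster_rt_sd``
    the fixed within-cluster RT standard deviation (seconds); ``prior_mean_sd``
    the prior standard deviation of cluster locations (defaults to the span of
    observed RTs when None). ``n_samples`` Gibbs samples are kept after
    ``burn_in`` discarded sweeps; ``seed`` fixes the chain.
    """

    concentration: float = 1.0
    cluster_rt_sd: float = 2.0
    prior_mean_sd: Optional[float] = None
    n_samples: int = 1000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ParameterError(f"concentration must be positive, got {self.concentration}")
        if self.cluster_rt_sd <= 0:
            raise ParameterError(f"cluster_rt_sd must be positive, got {self.cluster_rt_sd}")
        if self.prior_mean_sd is not None and self.prior_mean_sd <= 0:
            raise ParameterError(f"prior_mean_sd must be positive, got {self.prior_mean_sd}")
        if self.n_samples < 1:
            raise ParameterError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.burn_in < 0:
            raise ParameterError(f"burn_in must be >= 0, got {self.burn_in}")


def pearson_shape_correlation(shape_a: Optional[ShapeTrace], shape_b: Optional[ShapeTrace]) -> float:
    """Pearson correlation of two chromatographic traces on a common grid.

    Both traces are linearly interpolated onto the union of their scan
    times restricted to the overlapping RT range. Returns NaN — which fails
    any threshold — when either trace is missing, fewer than 3 grid points
    overlap, or either interpolated signal has zero variance.
    """
    if not shape_a or not shape_b:
        return float("nan")
    ta = np.array([t for t, _ in shape_a])
    sa = np.array([s for _, s in shape_a])
    tb = np.array([t for t, _ in shape_b])
    sb = np.array([s for _, s in shape_b])
    lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if hi <= lo:
        return float("nan")
    grid = np.union1d(ta, tb)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 3:
        return float("nan")
    ya = np.interp(grid, ta, sa)
    yb = np.interp(grid, tb, sb)
    if np.ptp(ya) == 0 or np.ptp(yb) == 0:
        return float("nan")
    ya = ya - ya.mean()
    yb = yb - yb.mean()
    return float(ya @ yb / math.sqrt((ya @ ya) * (yb @ yb)))


def greedy_group(run: PeakList, params: GreedyGroupingParams) -> MembershipMatrix:
    """Greedy intensity-seeded RT clustering; returns a binary partition.

    Seeds are taken in strictly decreasing intensity among unclustered peaks
    (ties broken by ascending peak id, for determinism). A candidate joins
    the seed's cluster iff it is unclustered, |rt - rt_seed| <= g_tol, and —
    when a correlation threshold is set — the Pearson correlation of its
    shape trace with the seed's trace strictly exceeds the threshold (peaks
    lacking traces fail the filter). Seeding depends only on intensity and
    id, so permuting the input row order leaves the partition unchanged.
    """
    n = run.size
    labels = np.full(n, -1, dtype=np.intp)
    order = sorted(range(n), key=lambda i: (-run[i].intensity, run[i].id))
    next_label = 0
    for seed_idx in order:
        if labels[seed_idx] != -1:
            continue
        seed = run[seed_idx]
        labels[seed_idx] = next_label
        for j in order:
            if labels[j] != -1:
                continue
            cand = run[j]
            if abs(cand.rt - seed.rt) > params.g_tol:
                continue
            if params.corr_threshold is not None:
                corr = pearson_shape_correlation(seed.shape, cand.shape)
                if not (corr > params.corr_threshold):  # NaN fails
                    continue
            labels[j] = next_label
        next_label += 1
    return MembershipMatrix.from_labels(labels)


def _log_norm_pdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (math.log(2.0 * math.pi * var) + (x - mean) ** 2 / var)


def mixture_group(run: PeakList, params: MixtureParams) -> MembershipMatrix:
    """Collapsed Gibbs sampling of a DP Gaussian mixture on retention time.

    Model: cluster means mu_k ~ Normal(mu_0, s0^2) with mu_0 the empirical
    RT mean and s0 = ``prior_mean_sd`` (default: the span of observed RTs);
    peak RTs t_i ~ Normal(mu_k, cluster_rt_sd^2); cluster assignments follow
    a Chinese-restaurant process with the given concentration. Means are
    integrated out analytically, so each sweep resamples every assignment
    from its collapsed conditional. The returned matrix holds empirical
    co-assignment frequencies across the kept samples (diagonal zero).
    Identical (run, params) including seed gives a bit-identical matrix.
    """
    n = run.size
    if n == 0:
        return MembershipMatrix(np.zeros((0, 0)), mode="probabilistic")
    t = np.array([p.rt for p in run])
    if n == 1:
        return MembershipMatrix(np.zeros((1, 1)), mode="probabilistic")

    var = params.cluster_rt_sd**2
    mu0 = float(t.mean())
    s0 = params.prior_mean_sd
    if s0 is None:
        s0 = max(float(t.max() - t.min()), params.cluster_rt_sd)
    s0_var = s0**2
    alpha = params.concentration
    rng = np.random.default_rng(params.seed)

    # compact cluster bookkeeping: parallel count/sum lists, swap-pop on death
    labels = np.zeros(n, dtype=np.intp)  # labels index into counts/sums
    counts: list[int] = [n]
    sums: list[float] = [float(t.sum())]
    log_2pi = math.log(2.0 * math.pi)

    co_counts = np.zeros((n, n))
    total = params.burn_in + params.n_samples
    for sweep in range(total):
        for i in range(n):
            old = labels[i]
            counts[old] -= 1
            sums[old] -= t[i]
            if counts[old] == 0:
                last = len(counts) - 1
                if old != last:
                    counts[old] = counts[last]
                    sums[old] = sums[last]
                    labels[labels == last] = old
                counts.pop()
                sums.pop()

            nk = np.array(counts, dtype=float)
            sk = np.array(sums, dtype=float)
            lam = 1.0 / s0_var + nk / var
            mu_n = (mu0 / s0_var + sk / var) / lam
            pred_var = var + 1.0 / lam
            log_w = np.log(nk) - 0.5 * (np.log(pred_var) + log_2pi + (t[i] - mu_n) ** 2 / pred_var)
            log_new = math.log(alpha) + _log_norm_pdf(t[i], mu0, var + s0_var)
            log_w = np.append(log_w, log_new)

            w = np.exp(log_w - log_w.max())
            cdf = np.cumsum(w)
            choice = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
            if choice == len(counts):
                counts.append(1)
                sums.append(float(t[i]))
            else:
                counts[choice] += 1
                sums[choice] += t[i]
            labels[i] = choice

        if sweep >= params.burn_in:
            co_counts += labels[:, None] == labels[None, :]

    matrix = co_counts / params.n_samples
    np.fill_diagonal(matrix, 0.0)
    return MembershipMatrix(matrix, mode="probabilistic")
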