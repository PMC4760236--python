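"""Thresholded Mahalanobis peak similarity between two runs.

Each peak is treated as the vector [m/z, RT]. With a diagonal covariance
of tolerances (sigma_m^2, sigma_t^2), the distance between a peak in run A
and one in run B is

    D(p_i, p_j) = sqrt((dm / sigma_m)^2 + (dt / sigma_t)^2),

computed only for pairs whose raw m/z and RT differences are within the
tolerance windows — the windows are hard thresholds that define the
solution space. The similarity score is one minus the normalized distance,

    W(p_i, p_j) = 1 - D(p_i, p_j) / D_max,

where D_max is the maximum distance among the computed (in-window) pairs
of the run pair being aligned, so W entries live in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, Tuple

import numpy as np
from scipy import sparse

from .errors import DimensionError, ParameterError
from .peaks import Peak, PeakList


@dataclass(frozen=True)
class Tolerances:
    """Matching tolerances: sigma_m for m/z, sigma_t for RT (seconds).

    ``mz_unit`` selects absolute Thomson ("absolute") or parts-per-million
    ("ppm") interpretation of sigma_m. In ppm mode the absolute window at a
    pair is sigma_m * mz_a * 1e-6, anchored at the run-A peak's m/z.
    """

    sigma_m: float
    sigma_t: float
    mz_unit: str = "absolute"

    def __post_init__(self) -> None:
        if not (self.sigma_m > 0 and math.isfinite(self.sigma_m)):
            raise ParameterError(f"sigma_m must be positive, got {self.sigma_m}")
        if not (self.sigma_t > 0 and math.isfinite(self.sigma_t)):
            raise ParameterError(f"sigma_t must be positive, got {self.sigma_t}")
        if self.mz_unit not in ("absolute", "ppm"):
            raise ParameterError(f"mz_unit must be 'absolute' or 'ppm', got {self.mz_unit!r}")

    def absolute_sigma_m(self, mz_a: float) -> float:
        """The absolute m/z window, converting from ppm at mz_a if needed."""
        if self.mz_unit == "ppm":
            return self.sigma_m * mz_a * 1e-6
        return self.sigma_m


class ScoreMatrix:
    """Sparse rectangular matrix of pair scores between two runs.

    Stored entries are (row, col, value) triplets; ``role`` tags whether
    the matrix holds raw similarities (``"W"``), cluster similarities
    (``"L"``) or the blended final scores (``"S"``). For role W, ``d_max``
    records the maximum in-window distance used for normalization.
    """

    def __init__(self, shape, rows, cols, values, role: str, d_max: float | None = None):
        self.shape: Tuple[int, int] = (int(shape[0]), int(shape[1]))
        self.rows = np.asarray(rows, dtype=np.intp)
        self.cols = np.asarray(cols, dtype=np.intp)
        self.values = np.asarray(values, dtype=float)
        if not (len(self.rows) == len(self.cols) == len(self.values)):
            raise DimensionError("rows, cols and values must have equal length")
        self.role = role
        self.d_max = d_max
        # canonical (row, col) order so equal matrices compare equal
        order = np.lexsort((self.cols, self.rows))
        self.rows, self.cols, self.values = self.rows[order], self.cols[order], self.values[order]

    @property
    def nnz(self) -> int:
        return len(self.values)

    def entries(self) -> Iterator[Tuple[int, int, float]]:
        for i, j, v in zip(self.rows, self.cols, self.values):
            yield int(i), int(j), float(v)

    def to_dict(self) -> Dict[Tuple[int, int], float]:
        return {(int(i), int(j)): float(v) for i, j, v in zip(self.rows, self.cols, self.values)}

    def to_csr(self) -> sparse.csr_matrix:
        # explicit zeros are legal entries (the worst in-window pair scores 0)
        return sparse.csr_matrix(
            (self.values, (self.rows, self.cols)), shape=self.shape
        )

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape)
        dense[self.rows, self.cols] = self.values
        return dense

    def max_value(self) -> float:
        return float(self.values.max()) if self.nnz else 0.0

    def __repr__(self) -> str:
        return f"ScoreMatrix(role={self.role!r}, shape={self.shape}, nnz={self.nnz})"


def mahalanobis_distance(peak_a: Peak, peak_b: Peak, tol: Tolerances) -> float:
    """Tolerance-scaled distance between two peaks in (m/z, RT) space.

    Zero iff both coordinates coincide; symmetric in absolute mode. In ppm
    mode the m/z scale is anchored at ``peak_a``'s m/z.
    """
    sm = tol.absolute_sigma_m(peak_a.mz)
    dm = (peak_a.mz - peak_b.mz) / sm
    dt = (peak_a.rt - peak_b.rt) / tol.sigma_t
    return math.hypot(dm, dt)


def build_W(run_a: PeakList, run_b: PeakList, tol: Tolerances) -> ScoreMatrix:
    """Build the sparse similarity matrix W between two runs.

    An entry (i, j) is stored iff |mz_i - mz_j| <= sigma_m (after ppm
    conversion) and |rt_i - rt_j| <= sigma_t. Stored entries equal
    1 - D/D_max over the in-window distances. Degenerate normalizations
    (a single candidate pair, or all distances zero) score 1 so that an
    in-window pair always remains matchable.
    """
    n_a, n_b = run_a.size, run_b.size
    if n_a == 0 or n_b == 0:
        return ScoreMatrix((n_a, n_b), [], [], [], role="W", d_max=None)

    mz_b = np.array([p.mz for p in run_b])
    rt_b = np.array([p.rt for p in run_b])
    order_b = np.argsort(mz_b, kind="stable")
    mz_b_sorted = mz_b[order_b]

    rows, cols, dists = [], [], []
    for i, pa in enumerate(run_a):
        sm = tol.absolute_sigma_m(pa.mz)
        lo = np.searchsorted(mz_b_sorted, pa.mz - sm, side="left")
        hi = np.searchsorted(mz_b_sorted, pa.mz + sm, side="right")
        for j in order_b[lo:hi]:
            if abs(pa.rt - rt_b[j]) <= tol.sigma_t:
                dm = (pa.mz - mz_b[j]) / sm
                dt = (pa.rt - rt_b[j]) / tol.sigma_t
                rows.append(i)
                cols.append(int(j))
                dists.append(math.hypot(dm, dt))

    if not rows:
        return ScoreMatrix((n_a, n_b), [], [], [], role="W", d_max=None)

    dists_arr = np.asarray(dists)
    d_max = float(dists_arr.max())
    if len(dists_arr) == 1 or d_max == 0.0:
        values = np.ones_like(dists_arr)
    else:
        values = 1.0 - dists_arr / d_max
    return ScoreMatrix((n_a, n_b), rows, cols, values, role="W", d_max=d_max)
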