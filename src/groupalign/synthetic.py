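"""Seeded generator of paired LC/MS runs with exact ground truth.

Each simulated compound produces a *group* of related peaks: a base ion
plus an isotope ladder (default spacing 1.003 Th) with geometrically
decaying intensity, all coeluting at the compound's retention time up to a
small jitter. Run B is derived from run A by a smooth, strictly monotonic
RT warp (t' = t + A*sin(pi*t/t_max)) plus a compound-level RT shift,
independent per-peak m/z and RT noise, and independent peak dropout —
emulating the premise that groups of coeluting related peaks are preserved
across runs while retention drifts nonlinearly between them.

``generate_confusable_pair`` additionally plants pairs of near-isobaric
compounds: two compounds share a base m/z and elute a few seconds apart,
so their base peaks are mutually confusable under the matching tolerances,
while each carries satellites at distinct spacings (isotope ladder vs a
charge-reduced ladder) that only match their true counterparts — the
scenario where raw similarity is ambiguous but group context is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .grouping import MembershipMatrix
from .peaks import GroundTruth, Peak, PeakList


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the paired-run simulator.

    Units: m/z quantities in Thomson, RT quantities in seconds.
    """

    n_compounds: int = 40
    peaks_per_group: Tuple[int, int] = (2, 4)
    mz_base_range: Tuple[float, float] = (100.0, 900.0)
    rt_range: Tuple[float, float] = (100.0, 1100.0)
    isotope_spacing: float = 1.003
    group_rt_jitter_sd: float = 0.3
    cross_run_mz_noise_sd: float = 0.002
    cross_run_rt_noise_sd: float = 0.3
    compound_rt_shift_sd: float = 2.0
    warp_amplitude: float = 20.0
    dropout_prob: float = 0.1
    intensity_decay: float = 0.6
    n_confusable: Optional[int] = None  # None -> n_compounds // 4 planted pairs
    confusable_rt_offset: float = 4.0
    confusable_satellite_spacing: float = 0.335
    with_shapes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 0:
            raise ParameterError("n_compounds must be non-negative")
        lo, hi = self.peaks_per_group
        if not (1 <= lo <= hi):
            raise ParameterError(f"peaks_per_group must satisfy 1 <= min <= max, got {self.peaks_per_group}")
        for name in ("mz_base_range", "rt_range"):
            a, b = getattr(self, name)
            if not a < b:
                raise ParameterError(f"{name} must be an ordered range, got {(a, b)}")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ParameterError(f"dropout_prob must lie in [0, 1), got {self.dropout_prob}")
        for name in ("group_rt_jitter_sd", "cross_run_mz_noise_sd", "cross_run_rt_noise_sd",
                     "compound_rt_shift_sd", "warp_amplitude"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not (0 < self.intensity_decay <= 1):
            raise ParameterError(f"intensity_decay must lie in (0, 1], got {self.intensity_decay}")
        if self.warp_amplitude > 0:
            # strict monotonicity of t + A*sin(pi*t/t_max): needs A*pi/t_max < 1
            if self.warp_amplitude * math.pi / self.rt_range[1] >= 1.0:
                raise ParameterError(
                    "warp_amplitude too large for a strictly monotonic warp "
                    f"(requires amplitude < rt_max/pi = {self.rt_range[1] / math.pi:.1f})"
                )
        if self.n_confusable is not None and (
            self.n_confusable < 0 or 2 * self.n_confusable > self.n_compounds
        ):
            raise ParameterError("n_confusable must satisfy 0 <= 2*n_confusable <= n_compounds")
        if self.confusable_rt_offset <= 0:
            raise ParameterError("confusable_rt_offset must be positive")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")


@dataclass(frozen=True)
class SyntheticPair:
    """A generated two-run instance with exact truth."""

    run_a: PeakList
    run_b: PeakList
    truth: GroundTruth
    membership_a: MembershipMatrix
    membership_b: MembershipMatrix


def warp_rt(t: np.ndarray, amplitude: float, t_max: float) -> np.ndarray:
    """Smooth nonlinear monotonic RT drift: t + amplitude*sin(pi*t/t_max)."""
    return t + amplitude * np.sin(np.pi * np.asarray(t, dtype=float) / t_max)


def _gaussian_trace(rt: float, intensity: float, width: float = 4.0, n: int = 9) -> Tuple[Tuple[float, float], ...]:
    grid = np.linspace(rt - 2.5 * width, rt + 2.5 * width, n)
    sig = intensity * np.exp(-0.5 * ((grid - rt) / width) ** 2)
    return tuple(zip(grid.tolist(), sig.tolist()))


def _generate(config: SyntheticConfig, n_confusable: int) -> SyntheticPair:
    rng = np.random.default_rng(config.seed)
    t_max = config.rt_range[1]

    # --- compound layout in run A ---------------------------------------
    # Each entry: (compound label, mz, rt, intensity) per member peak.
    mz_a: List[float] = []
    rt_a: List[float] = []
    inten_a: List[float] = []
    compound: List[int] = []
    trace_width: List[float] = []

    def add_compound(label: int, base_mz: float, base_rt: float, spacing: float) -> None:
        k = int(rng.integers(config.peaks_per_group[0], config.peaks_per_group[1] + 1))
        base_intensity = float(10 ** rng.uniform(5.0, 7.0))
        width = float(rng.uniform(3.0, 6.0))
        for j in range(k):
            mz_a.append(base_mz + j * spacing)
            rt_a.append(base_rt + float(rng.normal(0.0, config.group_rt_jitter_sd)))
            inten_a.append(base_intensity * config.intensity_decay**j)
            compound.append(label)
            trace_width.append(width)

    label = 0
    for _ in range(n_confusable):
        base_mz = float(rng.uniform(*config.mz_base_range))
        base_rt = float(rng.uniform(config.rt_range[0], config.rt_range[1] - config.confusable_rt_offset))
        add_compound(label, base_mz, base_rt, config.isotope_spacing)
        add_compound(label + 1, base_mz, base_rt + config.confusable_rt_offset,
                     config.confusable_satellite_spacing)
        label += 2
    for _ in range(config.n_compounds - 2 * n_confusable):
        add_compound(label, float(rng.uniform(*config.mz_base_range)),
                     float(rng.uniform(*config.rt_range)), config.isotope_spacing)
        label += 1

    n = len(mz_a)
    order_a = rng.permutation(n)

    peaks_a: List[Peak] = []
    labels_a: List[int] = []
    for rank, idx in enumerate(order_a):
        shape = _gaussian_trace(rt_a[idx], inten_a[idx], trace_width[idx]) if config.with_shapes else None
        peaks_a.append(Peak(f"a{rank:04d}", mz_a[idx], max(rt_a[idx], 0.0), inten_a[idx], shape=shape))
        labels_a.append(compound[idx])
    run_a = PeakList("run_a", peaks_a)
    membership_a = (
        MembershipMatrix.from_labels(labels_a) if n else MembershipMatrix.zeros(0)
    )

    # --- derive run B ----------------------------------------------------
    n_labels = label
    shifts = rng.normal(0.0, config.compound_rt_shift_sd, size=max(n_labels, 1))
    keep = rng.random(n) >= config.dropout_prob

    surv_indices = [int(i) for i in order_a if keep[i]]  # traverse in run-A order
    order_b = rng.permutation(len(surv_indices))

    mz_noise = rng.normal(0.0, config.cross_run_mz_noise_sd, size=n)
    rt_noise = rng.normal(0.0, config.cross_run_rt_noise_sd, size=n)
    inten_factor = np.exp(rng.normal(0.0, 0.1, size=n))

    peaks_b: List[Peak] = []
    labels_b: List[int] = []
    pairs: List[Tuple[str, str]] = []
    for rank, pos in enumerate(order_b):
        idx = surv_indices[pos]
        c = compound[idx]
        rt_b = float(warp_rt(np.array([rt_a[idx]]), config.warp_amplitude, t_max)[0]
                     + shifts[c] + rt_noise[idx])
        mz_b = mz_a[idx] + float(mz_noise[idx])
        inten_b = inten_a[idx] * float(inten_factor[idx])
        shape = _gaussian_trace(rt_b, inten_b, trace_width[idx]) if config.with_shapes else None
        pid = f"b{rank:04d}"
        peaks_b.append(Peak(pid, mz_b, max(rt_b, 0.0), inten_b, shape=shape))
        labels_b.append(c)
        a_rank = int(np.nonzero(order_a == idx)[0][0])
        pairs.append((f"a{a_rank:04d}", pid))
    run_b = PeakList("run_b", peaks_b)
    membership_b = (
        MembershipMatrix.from_labels(labels_b) if labels_b else MembershipMatrix.zeros(0)
    )

    truth = GroundTruth(pairs, run_a, run_b)
    return SyntheticPair(run_a, run_b, truth, membership_a, membership_b)


def generate_pair(config: SyntheticConfig) -> SyntheticPair:
    """Generate a paired-run instance with ordinary (non-confusable) compounds."""
    return _generate(config, n_confusable=0)


def generate_confusable_pair(config: SyntheticConfig) -> SyntheticPair:
    """Generate a paired-run instance planting ``config.n_confusable`` confusable
    compound pairs (default: a quarter of the compounds, in pairs); with zero
    planted pairs this reduces to :func:`generate_pair`."""
    n_conf = config.n_confusable
    if n_conf is None:
        n_conf = config.n_compounds // 4
    return _generate(config, n_confusable=n_conf)
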