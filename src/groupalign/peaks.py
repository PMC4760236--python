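"""Domain types: peaks, runs, ground-truth correspondences and matchings.

A *peak* (feature) is one detected ion signal, summarised by its
mass-to-charge ratio (m/z, in Thomson), retention time (RT, in seconds)
and intensity, optionally carrying a sampled chromatographic shape trace.
A *run* is the peak list extracted from one LC/MS analysis of one sample.
Alignment pairs peaks across two runs that originate from the same analyte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Tuple

from .errors import ValidationError

# A chromatographic trace: (scan RT in seconds, signal) samples.
ShapeTrace = Tuple[Tuple[float, float], ...]


@dataclass(frozen=True)
class Peak:
    """One detected LC/MS feature.

    Parameters
    ----------
    id : str
        Identifier, unique within its run.
    mz : float
        Mass-to-charge ratio in Thomson; strictly positive.
    rt : float
        Retention time in seconds; non-negative.
    intensity : float
        Abundance in arbitrary units; non-negative.
    shape : tuple of (rt_scan, signal), optional
        Samples of the chromatographic trace, with strictly increasing
        scan times. Absent for most centroided exports.
    """

    id: str
    mz: float
    rt: float
    intensity: float
    shape: Optional[ShapeTrace] = None

    def __post_init__(self) -> None:
        if not (self.mz > 0 and math.isfinite(self.mz)):
            raise ValidationError(f"peak {self.id!r}: mz must be positive, got {self.mz}")
        if not (self.rt >= 0 and math.isfinite(self.rt)):
            raise ValidationError(f"peak {self.id!r}: rt must be non-negative, got {self.rt}")
        if not (self.intensity >= 0 and math.isfinite(self.intensity)):
            raise ValidationError(
                f"peak {self.id!r}: intensity must be non-negative, got {self.intensity}"
            )
        if self.shape is not None:
            object.__setattr__(self, "shape", tuple((float(t), float(s)) for t, s in self.shape))
            times = [t for t, _ in self.shape]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError(
                    f"peak {self.id!r}: shape scan times must be strictly increasing"
                )


class PeakList:
    """An ordered collection of peaks from one run, with unique ids."""

    def __init__(self, run_id: str, peaks: Iterable[Peak]):
        self.run_id = run_id
        self.peaks: Tuple[Peak, ...] = tuple(peaks)
        index: dict[str, int] = {}
        for i, p in enumerate(self.peaks):
            if p.id in index:
                raise ValidationError(f"run {run_id!r}: duplicate peak id {p.id!r}")
            index[p.id] = i
        self._index = index

    @property
    def size(self) -> int:
        return len(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self._index

    def index_of(self, peak_id: str) -> int:
        try:
            return self._index[peak_id]
        except KeyError:
            raise ValidationError(
                f"run {self.run_id!r}: unknown peak id {peak_id!r}"
            ) from None

    def by_id(self, peak_id: str) -> Peak:
        return self.peaks[self.index_of(peak_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakList):
            return NotImplemented
        return self.run_id == other.run_id and self.peaks == other.peaks

    def __repr__(self) -> str:
        return f"PeakList(run_id={self.run_id!r}, size={self.size})"


class GroundTruth:
    """A one-to-one set of known peak correspondences between two runs.

    ``pairs`` holds ``(id_a, id_b)`` tuples; ``covered_a`` / ``covered_b``
    are the per-run id sets appearing in any pair. Many-to-many inputs are
    rejected: each id may appear in at most one pair.
    """

    def __init__(
        self,
        pairs: Iterable[Tuple[str, str]],
        run_a: Optional[PeakList] = None,
        run_b: Optional[PeakList] = None,
    ):
        pair_list = [(str(a), str(b)) for a, b in pairs]
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b in pair_list:
            if a in seen_a:
                raise ValidationError(f"ground truth: id {a!r} appears in more than one pair")
            if b in seen_b:
                raise ValidationError(f"ground truth: id {b!r} appears in more than one pair")
            seen_a.add(a)
            seen_b.add(b)
        if run_a is not None:
            for a, _ in pair_list:
                if a not in run_a:
                    raise ValidationError(
                        f"ground truth: id {a!r} not found in run {run_a.run_id!r}"
                    )
        if run_b is not None:
            for _, b in pair_list:
                if b not in run_b:
                    raise ValidationError(
                        f"ground truth: id {b!r} not found in run {run_b.run_id!r}"
                    )
        self.pairs: frozenset[Tuple[str, str]] = frozenset(pair_list)
        self.covered_a: frozenset[str] = frozenset(seen_a)
        self.covered_b: frozenset[str] = frozenset(seen_b)

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.pairs == other.pairs

    def __repr__(self) -> str:
        return f"GroundTruth(n_pairs={len(self.pairs)})"


class Matching:
    """A one-to-one alignment result: matched id pairs plus the total score."""

    def __init__(self, pairs: Iterable[Tuple[str, str, float]]):
        pair_list = [(str(a), str(b), float(s)) for a, b, s in pairs]
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b, _ in pair_list:
            if a in seen_a or b in seen_b:
                raise ValidationError("matching is not one-to-one")
            seen_a.add(a)
            seen_b.add(b)
        self.scored_pairs: Tuple[Tuple[str, str, float], ...] = tuple(
            sorted(pair_list, key=lambda e: (e[0], e[1]))
        )
        self.pairs: frozenset[Tuple[str, str]] = frozenset((a, b) for a, b, _ in pair_list)
        self.total_score: float = float(sum(s for _, _, s in pair_list))

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Matching):
            return NotImplemented
        if self.pairs != other.pairs:
            return False
        theirs = {(a, b): s for a, b, s in other.scored_pairs}
        return all(
            math.isclose(s, theirs[(a, b)], rel_tol=1e-9, abs_tol=1e-12)
            for a, b, s in self.scored_pairs
        )

    def __repr__(self) -> str:
        return f"Matching(n_pairs={len(self.pairs)}, total_score={self.total_score:.6g})"
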