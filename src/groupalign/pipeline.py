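"""End-to-end alignment pipeline and parameter sweeps.

The pipeline wires the stages together:

    build_W -> (optional) group both runs -> cluster_similarity -> combine
            -> greedy (or exact) matching

Grouping method "none" reproduces plain maximum-weight matching on W (MW);
"greedy" and "mixture" add cluster similarity (MWG / MWM respectively).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from itertools import product
from typing import List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import ParameterError
from .evaluation import EvaluationResult, evaluate
from .grouping import (
    GreedyGroupingParams,
    MembershipMatrix,
    MixtureParams,
    greedy_group,
    mixture_group,
)
from .matching import BipartiteInstance, exact_match, greedy_match
from .peaks import GroundTruth, Matching, PeakList
from .scoring import BlendWeight, cluster_similarity, combine
from .similarity import Tolerances, build_W

logger = logging.getLogger("groupalign")

GROUPING_METHODS = ("none", "greedy", "mixture")


@dataclass(frozen=True)
class AlignmentConfig:
    """Full configuration of one alignment: tolerances, blending, grouping, matcher."""

    tolerances: Tolerances = field(default_factory=lambda: Tolerances(sigma_m=0.01, sigma_t=30.0))
    alpha: float = 0.3
    grouping: str = "none"  # none | greedy | mixture
    greedy_params: GreedyGroupingParams = field(default_factory=lambda: GreedyGroupingParams(g_tol=2.0))
    mixture_params: MixtureParams = field(default_factory=MixtureParams)
    matcher: str = "greedy"  # greedy | exact
    normalize_L: bool = True
    include_zero_edges: bool = False
    exact_max_size: int = 2000

    def __post_init__(self) -> None:
        if self.grouping not in GROUPING_METHODS:
            raise ParameterError(f"grouping must be one of {GROUPING_METHODS}, got {self.grouping!r}")
        if self.matcher not in ("greedy", "exact"):
            raise ParameterError(f"matcher must be 'greedy' or 'exact', got {self.matcher!r}")
        BlendWeight(self.alpha)  # validates range


def group_run(run: PeakList, config: AlignmentConfig) -> Optional[MembershipMatrix]:
    if config.grouping == "none":
        return None
    if config.grouping == "greedy":
        return greedy_group(run, config.greedy_params)
    return mixture_group(run, config.mixture_params)


def align(
    run_a: PeakList,
    run_b: PeakList,
    config: AlignmentConfig,
    membership_a: Optional[MembershipMatrix] = None,
    membership_b: Optional[MembershipMatrix] = None,
) -> Matching:
    """Align two runs; returns the matched id pairs with their scores.

    Precomputed membership matrices (e.g. from an external grouping tool,
    or the simulator's ground truth) can be passed in; otherwise they are
    derived with the configured grouping method. With grouping "none" the
    result is the plain maximum-weight matching on W.
    """
    t0 = time.perf_counter()
    W = build_W(run_a, run_b, config.tolerances)
    logger.info("W: shape=%s nnz=%d d_max=%s", W.shape, W.nnz, W.d_max)

    if config.grouping == "none" and membership_a is None:
        S = W
    else:
        c_a = membership_a if membership_a is not None else group_run(run_a, config)
        c_b = membership_b if membership_b is not None else group_run(run_b, config)
        L = cluster_similarity(W, c_a, c_b)
        logger.info("L: nnz=%d max=%.4g", L.nnz, L.max_value())
        S = combine(W, L, BlendWeight(config.alpha), normalize_L=config.normalize_L)

    instance = BipartiteInstance.from_score_matrix(S, include_zero=config.include_zero_edges)
    if config.matcher == "exact":
        result = exact_match(instance, max_size=config.exact_max_size)
    else:
        result = greedy_match(instance)
    matching = result.to_matching(run_a, run_b, S)
    logger.info(
        "matched %d pairs, total score %.4g (%.3fs)",
        len(matching), matching.total_score, time.perf_counter() - t0,
    )
    return matching


def align_and_evaluate(
    run_a: PeakList,
    run_b: PeakList,
    truth: GroundTruth,
    config: AlignmentConfig,
    membership_a: Optional[MembershipMatrix] = None,
    membership_b: Optional[MembershipMatrix] = None,
) -> Tuple[Matching, EvaluationResult]:
    matching = align(run_a, run_b, config, membership_a, membership_b)
    return matching, evaluate(matching, truth)


def _configs_from_grid(base: AlignmentConfig, grid: Mapping[str, Sequence]) -> List[Tuple[dict, AlignmentConfig]]:
    """Expand a flat parameter grid into configs.

    Recognised grid keys: sigma_m, sigma_t, mz_unit, alpha, grouping, g_tol,
    corr_threshold, matcher.
    """
    if not grid:
        raise ParameterError("sweep grid must be non-empty")
    keys = list(grid)
    combos = []
    for values in product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        tol = Tolerances(
            sigma_m=point.get("sigma_m", base.tolerances.sigma_m),
            sigma_t=point.get("sigma_t", base.tolerances.sigma_t),
            mz_unit=point.get("mz_unit", base.tolerances.mz_unit),
        )
        greedy_params = GreedyGroupingParams(
            g_tol=point.get("g_tol", base.greedy_params.g_tol),
            corr_threshold=point.get("corr_threshold", base.greedy_params.corr_threshold),
        )
        cfg = replace(
            base,
            tolerances=tol,
            alpha=point.get("alpha", base.alpha),
            grouping=point.get("grouping", base.grouping),
            greedy_params=greedy_params,
            matcher=point.get("matcher", base.matcher),
        )
        combos.append((point, cfg))
    return combos


def sweep(
    run_pairs: Sequence[Tuple[PeakList, PeakList, GroundTruth]],
    grid: Mapping[str, Sequence],
    base: Optional[AlignmentConfig] = None,
) -> pd.DataFrame:
    """Full-factorial evaluation over a parameter grid and a set of run pairs.

    Returns one row per (pair, grid point) with the grid values, counts and
    precision/recall/F1; deterministic given fixed seeds in the base config.
    """
    base = base or AlignmentConfig()
    combos = _configs_from_grid(base, grid)
    rows = []
    for pair_idx, (run_a, run_b, truth) in enumerate(run_pairs):
        for point, cfg in combos:
            _, result = align_and_evaluate(run_a, run_b, truth, cfg)
            row = {"pair": pair_idx, **point, **result.as_dict()}
            rows.append(row)
    return pd.DataFrame(rows)


def best_rows(table: pd.DataFrame) -> pd.DataFrame:
    """The best-F1 grid point per run pair (first in table order on ties)."""
    idx = table.groupby("pair")["f1"].idxmax()
    return table.loc[idx].reset_index(drop=True)
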