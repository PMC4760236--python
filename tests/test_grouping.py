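import math

import numpy as np
import pytest

from groupalign import (
    GreedyGroupingParams,
    MembershipMatrix,
    MixtureParams,
    ParameterError,
    Peak,
    PeakList,
    greedy_group,
    mixture_group,
    pearson_shape_correlation,
)
from helpers import dp_partition_posterior


def run_from(rows, with_shape=False):
    peaks = []
    for pid, rt, intensity, *rest in rows:
        shape = rest[0] if rest else None
        peaks.append(Peak(pid, 100.0, rt, intensity, shape=shape))
    return PeakList("r", peaks)


class TestGreedyGroup:
    def test_single_peak_zero_matrix(self):
        mm = greedy_group(run_from([("p1", 10.0, 5.0)]), GreedyGroupingParams(g_tol=1.0))
        assert mm.matrix.shape == (1, 1) and mm.matrix[0, 0] == 0.0

    def test_hand_traced_two_clusters(self, small_run):
        # p1 (most intense) seeds; p2 within 1 s; p3 seeds alone
        mm = greedy_group(small_run, GreedyGroupingParams(g_tol=1.0))
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1.0
        assert np.array_equal(mm.matrix, expected)

    def test_all_gaps_exceed_gtol_all_singletons(self):
        run = run_from([("p1", 0.0, 3.0), ("p2", 10.0, 2.0), ("p3", 20.0, 1.0)])
        mm = greedy_group(run, GreedyGroupingParams(g_tol=1.0))
        assert not mm.matrix.any()

    def test_window_centred_on_seed_not_cluster(self):
        # p2 is within g_tol of p1 (seed); p3 within g_tol of p2 but not p1 -> excluded
        run = run_from([("p1", 10.0, 100.0), ("p2", 10.9, 50.0), ("p3", 11.8, 40.0)])
        mm = greedy_group(run, GreedyGroupingParams(g_tol=1.0))
        assert mm.matrix[0, 1] == 1.0 and mm.matrix[0, 2] == 0.0
        # p3 then seeds its own cluster alone (p2 already taken)
        assert mm.matrix[1, 2] == 0.0

    def test_partition_is_equivalence_relation(self, rng):
        run = run_from(
            [(f"p{i}", float(rng.uniform(0, 50)), float(rng.uniform(1, 100))) for i in range(40)]
        )
        mm = greedy_group(run, GreedyGroupingParams(g_tol=3.0))
        m = mm.matrix
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)
        full = m + np.eye(len(run))  # close the relation over the diagonal
        # transitivity: if i~j and j~k then i~k
        reach = (full @ full > 0).astype(float)
        assert np.array_equal(reach > 0, full > 0)

    def test_row_order_invariance(self, rng):
        rows = [(f"p{i}", float(rng.uniform(0, 30)), float(rng.uniform(1, 100))) for i in range(25)]
        run = run_from(rows)
        perm = rng.permutation(len(rows))
        run_shuffled = run_from([rows[i] for i in perm])
        mm = greedy_group(run, GreedyGroupingParams(g_tol=2.0))
        mm_shuffled = greedy_group(run_shuffled, GreedyGroupingParams(g_tol=2.0))
        # compare co-membership of the same id pairs
        for i in range(len(rows)):
            for j in range(len(rows)):
                assert mm.matrix[i, j] == mm_shuffled.matrix[
                    run_shuffled.index_of(rows[i][0]), run_shuffled.index_of(rows[j][0])
                ]

    def test_intensity_tie_broken_by_id(self):
        run = run_from([("pb", 10.0, 50.0), ("pa", 12.0, 50.0), ("pc", 11.0, 10.0)])
        mm = greedy_group(run, GreedyGroupingParams(g_tol=1.5))
        # 'pa' seeds first (tie on intensity, ascending id) and absorbs pc
        assert mm.matrix[1, 2] == 1.0 and mm.matrix[0, 2] == 0.0

    def test_corr_filter_requires_traces(self):
        trace = ((9.0, 1.0), (10.0, 5.0), (11.0, 1.0))
        run = run_from(
            [("p1", 10.0, 100.0, trace), ("p2", 10.2, 50.0, None)]
        )
        mm = greedy_group(run, GreedyGroupingParams(g_tol=1.0, corr_threshold=0.5))
        assert mm.matrix[0, 1] == 0.0  # p2 has no trace, fails the filter

    def test_corr_filter_accepts_correlated_trace(self):
        trace = ((9.0, 1.0), (10.0, 5.0), (11.0, 1.0))
        scaled = tuple((t, 3.0 * s) for t, s in trace)
        run = run_from([("p1", 10.0, 100.0, trace), ("p2", 10.2, 50.0, scaled)])
        mm = greedy_group(run, GreedyGroupingParams(g_tol=1.0, corr_threshold=0.5))
        assert mm.matrix[0, 1] == 1.0


class TestPearsonShapeCorrelation:
    trace = ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))

    def test_identical_traces(self):
        assert pearson_shape_correlation(self.trace, self.trace) == pytest.approx(1.0)

    def test_collinear_traces(self):
        doubled = tuple((t, 2 * s) for t, s in self.trace)
        assert pearson_shape_correlation(self.trace, doubled) == pytest.approx(1.0)

    def test_negated_trace(self):
        flipped = ((1.0, 3.0), (2.0, 2.0), (3.0, 1.0))
        assert pearson_shape_correlation(self.trace, flipped) == pytest.approx(-1.0)

    def test_resampling_on_union_grid(self):
        # second trace on a shifted grid inside the overlap; linear signals stay collinear
        other = ((1.5, 3.0), (2.5, 5.0), (3.0, 6.0))
        assert pearson_shape_correlation(self.trace, other) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a, b",
        [
            (None, trace),
            (trace, None),
            (((1.0, 1.0), (2.0, 2.0)), ((1.0, 1.0), (2.0, 2.0))),  # < 3 points
            (((1.0, 1.0), (2.0, 1.0), (3.0, 1.0)), trace),  # zero variance
            (((10.0, 1.0), (11.0, 2.0), (12.0, 1.0)), trace),  # disjoint RT ranges
        ],
    )
    def test_undefined_cases_fail_any_threshold(self, a, b):
        corr = pearson_shape_correlation(a, b)
        assert math.isnan(corr)
        assert not (corr > -1.0)  # NaN fails every threshold comparison


class TestMixtureGroup:
    def test_single_peak_zero_matrix(self):
        mm = mixture_group(run_from([("p1", 10.0, 1.0)]), MixtureParams(n_samples=10, burn_in=5))
        assert mm.matrix.shape == (1, 1) and mm.matrix[0, 0] == 0.0

    def test_same_seed_bit_identical(self):
        run = run_from([(f"p{i}", float(10 + 3 * i), 1.0) for i in range(8)])
        params = MixtureParams(seed=42, n_samples=200, burn_in=50)
        m1 = mixture_group(run, params)
        m2 = mixture_group(run, params)
        assert np.array_equal(m1.matrix, m2.matrix)

    def test_two_identical_rts_match_exact_posterior(self):
        params = MixtureParams(
            concentration=1.0, cluster_rt_sd=1.0, prior_mean_sd=10.0,
            n_samples=5000, burn_in=200, seed=5,
        )
        run = run_from([("p1", 50.0, 1.0), ("p2", 50.0, 1.0)])
        mm = mixture_group(run, params)
        exact = dp_partition_posterior([50.0, 50.0], 1.0, 1.0, 10.0)
        p = exact[0, 1]
        se = math.sqrt(p * (1 - p) / params.n_samples)
        assert abs(mm.matrix[0, 1] - p) < 3 * se + 1e-9

    def test_distant_rts_nearly_never_comembers(self):
        params = MixtureParams(
            concentration=1.0, cluster_rt_sd=1.0, prior_mean_sd=1000.0,
            n_samples=2000, burn_in=100, seed=6,
        )
        run = run_from([("p1", 0.0, 1.0), ("p2", 1000.0, 1.0)])
        mm = mixture_group(run, params)
        assert mm.matrix[0, 1] < 0.01

    def test_symmetric_zero_diagonal_in_unit_interval(self):
        run = run_from([(f"p{i}", float(i * 1.5), 1.0) for i in range(6)])
        mm = mixture_group(run, MixtureParams(n_samples=300, burn_in=50, seed=3))
        m = mm.matrix
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert m.min() >= 0 and m.max() <= 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"concentration": 0.0},
            {"cluster_rt_sd": -1.0},
            {"prior_mean_sd": 0.0},
            {"n_samples": 0},
            {"burn_in": -1},
        ],
    )
    def test_bad_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MixtureParams(**kwargs)


class TestMembershipMatrix:
    def test_from_labels_blocks(self):
        mm = MembershipMatrix.from_labels([0, 0, 1])
        assert mm.matrix[0, 1] == 1.0 and mm.matrix[0, 2] == 0.0
        assert np.all(np.diag(mm.matrix) == 0)

    def test_bad_gtol_rejected(self):
        with pytest.raises(ParameterError):
            GreedyGroupingParams(g_tol=0.0)
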