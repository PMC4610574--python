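"""Tests of the point-matching protocol and the recall/precision metrics."""

import numpy as np
import pytest

from inflocount import (
    aggregate_metrics,
    compute_metrics,
    default_radius,
    match_detections,
    MatchResult,
    MetricsReport,
)

from oracles import optimal_matching_tp


class TestMatchDetections:
    def test_perfect_single_match(self):
        m = match_detections([(10.0, 10.0)], [(10.0, 10.0)], radius=3.0)
        assert (m.TP, m.FP, m.FN) == (1, 0, 0)
        assert m.pairs == [(0, 0)]

    def test_redundant_detection_counts_as_false_positive(self):
        # two detections of one flower: the second is a redundant true
        # positive and scores as FP
        m = match_detections([(10.0, 10.0), (11.0, 10.0)], [(10.0, 10.0)], radius=3.0)
        assert (m.TP, m.FP, m.FN) == (1, 1, 0)

    def test_total_miss(self):
        m = match_detections([], [(0.0, 0.0), (5.0, 5.0), (9.0, 9.0)], radius=2.0)
        assert (m.TP, m.FP, m.FN) == (0, 0, 3)

    def test_detection_outside_radius_is_fp_and_fn(self):
        m = match_detections([(0.0, 0.0)], [(10.0, 10.0)], radius=2.0)
        assert (m.TP, m.FP, m.FN) == (0, 1, 1)

    def test_closest_pair_wins(self):
        # one truth, two detections: the nearer one becomes the TP
        m = match_detections([(0.0, 2.0), (0.0, 1.0)], [(0.0, 0.0)], radius=5.0)
        assert m.pairs == [(1, 0)]

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], radius=0.0)

    def test_accounting_conservation_fuzzed(self):
        """TP+FN = truths and TP+FP = detections on 500 random instances."""
        rng = np.random.default_rng(99)
        for _ in range(500):
            nd, nt = rng.integers(0, 25, 2)
            det = rng.uniform(0, 50, (nd, 2))
            tru = rng.uniform(0, 50, (nt, 2))
            radius = float(rng.uniform(0.5, 10.0))
            m = match_detections(det, tru, radius)
            assert m.TP + m.FN == nt
            assert m.TP + m.FP == nd
            assert m.TP == len(m.pairs)
            assert len({t for _, t in m.pairs}) == m.TP  # truths used once
            assert len({d for d, _ in m.pairs}) == m.TP  # detections used once

    def test_detection_order_does_not_change_counts(self):
        rng = np.random.default_rng(4)
        det = rng.uniform(0, 30, (15, 2))
        tru = rng.uniform(0, 30, (12, 2))
        base = match_detections(det, tru, 4.0)
        for _ in range(5):
            perm = rng.permutation(len(det))
            m = match_detections(det[perm], tru, 4.0)
            assert (m.TP, m.FP, m.FN) == (base.TP, base.FP, base.FN)

    def test_greedy_equals_optimal_for_separated_truths(self):
        """With truth spacing > 2·radius, greedy matching is optimal."""
        rng = np.random.default_rng(11)
        radius = 3.0
        for _ in range(200):
            tru = rng.uniform(0, 200, (rng.integers(2, 15), 2))
            diff = tru[:, None] - tru[None, :]
            dist = np.sqrt((diff**2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            tru = tru[dist.min(axis=1) > 2 * radius]
            det = rng.uniform(0, 200, (rng.integers(0, 20), 2))
            m = match_detections(det, tru, radius)
            assert m.TP == optimal_matching_tp(det, tru, radius)

    def test_greedy_near_optimal_on_general_instances(self):
        # exactness is only guaranteed for separated truths; on dense
        # random instances greedy must still never beat the optimum and
        # should match it on the vast majority
        rng = np.random.default_rng(12)
        equal = 0
        for _ in range(200):
            det = rng.uniform(0, 40, (rng.integers(0, 20), 2))
            tru = rng.uniform(0, 40, (rng.integers(0, 20), 2))
            m = match_detections(det, tru, 5.0)
            opt = optimal_matching_tp(det, tru, 5.0)
            assert m.TP <= opt
            equal += m.TP == opt
        assert equal >= 180  # >= 90% on deliberately crowded fields


class TestMetrics:
    def test_direct_substitution(self):
        rep = compute_metrics(MatchResult(TP=84, FP=6, FN=16, pairs=[]))
        assert rep.recall == pytest.approx(0.8400, abs=1e-4)
        assert rep.precision == pytest.approx(0.9333, abs=1e-4)

    def test_degenerate_counts_yield_missing_not_zero(self):
        rep = compute_metrics(MatchResult(TP=0, FP=0, FN=0, pairs=[]))
        assert rep.recall is None and rep.precision is None

    @pytest.mark.parametrize("n", [1, 7])
    def test_perfect_detector(self, n):
        rep = compute_metrics(MatchResult(TP=n, FP=0, FN=0, pairs=[]))
        assert rep.recall == 1.0 and rep.precision == 1.0

    def test_zero_detections_keep_recall_only(self):
        rep = compute_metrics(MatchResult(TP=0, FP=0, FN=4, pairs=[]))
        assert rep.recall == 0.0 and rep.precision is None


class TestAggregate:
    def test_unweighted_mean(self):
        reports = [MetricsReport(recall=0.8, precision=1.0),
                   MetricsReport(recall=0.9, precision=0.9)]
        agg = aggregate_metrics(reports)
        assert agg.mean_recall == pytest.approx(0.85)
        assert agg.mean_precision == pytest.approx(0.95)
        assert agg.n_images == 2

    def test_single_report_identity(self):
        agg = aggregate_metrics([MetricsReport(recall=0.7, precision=0.6)])
        assert agg.mean_recall == pytest.approx(0.7)
        assert agg.mean_precision == pytest.approx(0.6)

    def test_missing_values_skipped(self):
        reports = [MetricsReport(recall=0.8, precision=None),
                   MetricsReport(recall=None, precision=None),
                   MetricsReport(recall=0.9, precision=0.5)]
        agg = aggregate_metrics(reports)
        assert agg.mean_recall == pytest.approx(0.85)
        assert agg.mean_precision == pytest.approx(0.5)

    def test_all_missing_gives_missing(self):
        agg = aggregate_metrics([MetricsReport(), MetricsReport()])
        assert agg.mean_recall is None and agg.mean_precision is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_metrics([])


class TestDefaultRadius:
    def test_half_median_nearest_neighbour(self):
        # colinear points spaced 10 apart: NN distance 10 -> radius 5
        pts = [(0.0, 0.0), (0.0, 10.0), (0.0, 20.0), (0.0, 30.0)]
        assert default_radius(pts) == pytest.approx(5.0)

    def test_fallback_for_degenerate_truth(self):
        assert default_radius([(3.0, 3.0)]) == 5.0
        assert default_radius([]) == 5.0
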