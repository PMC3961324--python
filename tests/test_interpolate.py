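"""Closed-form continuous AUC-PR, discrete interpolations, and AUC-ROC."""

import numpy as np
import pytest

from conftest import pairwise_auc_roc, simpson_auc_pr, simpson_segment_auc
from softpr.core import ConfusionMatrix, InputError, WeightedSample, supporting_points
from softpr.interpolate import (
    Segment,
    auc_pr_continuous,
    auc_pr_discrete_fp,
    auc_pr_discrete_tp,
    auc_roc,
    dense_pr_curve,
    segment_auc,
)


def cm(tp, fp, r_fg, w_bg):
    return ConfusionMatrix(tp=tp, fp=fp, fn=r_fg - tp, tn=w_bg - fp, threshold=0.0)


class TestSegmentAuc:
    def test_perfect_segment_has_area_one(self):
        assert segment_auc(cm(1, 0, 1, 1), cm(0, 0, 1, 1), 1.0) == pytest.approx(1.0)

    def test_constant_precision_half(self):
        # tp/fp ratio equal at both ends -> horizontal piece at precision 0.5
        assert segment_auc(cm(2, 2, 2, 3), cm(1, 1, 2, 3), 2.0) == pytest.approx(0.25)

    def test_against_quadrature_oracle_single(self):
        val = segment_auc(cm(2, 3, 2, 3), cm(1, 1, 2, 3), 2.0)
        assert val == pytest.approx(simpson_segment_auc(1, 1, 2, 3, 2.0), abs=1e-9)

    def test_against_quadrature_oracle_random(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            r_fg = rng.uniform(1.0, 50.0)
            tp_a = rng.uniform(0.0, r_fg * 0.9)
            tp_b = rng.uniform(tp_a + 1e-3 * r_fg, r_fg)
            fp_a = rng.uniform(0.0, 100.0)
            fp_b = fp_a + rng.uniform(0.0, 100.0)
            w_bg = fp_b + 1.0
            got = segment_auc(cm(tp_b, fp_b, r_fg, w_bg), cm(tp_a, fp_a, r_fg, w_bg), r_fg)
            want = simpson_segment_auc(tp_a, fp_a, tp_b, fp_b, r_fg, n=10_000)
            assert got == pytest.approx(want, abs=1e-9)

    def test_zero_width_pair_rejected(self):
        with pytest.raises(ValueError, match="tp_A >= tp_B"):
            segment_auc(cm(1, 2, 2, 3), cm(1, 1, 2, 3), 2.0)

    def test_segment_reproduces_endpoint_precisions(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tp_a, d_tp = rng.uniform(0, 5), rng.uniform(0.01, 5)
            fp_a, d_fp = rng.uniform(0, 5), rng.uniform(0, 5)
            r_fg = tp_a + d_tp + rng.uniform(0, 3)
            s = d_fp / d_tp
            seg = Segment(
                a=1 + s,
                b=(fp_a - s * tp_a) / r_fg,
                pA=tp_a / r_fg,
                pB=(tp_a + d_tp) / r_fg,
            )
            if tp_a + fp_a > 0:
                assert seg.precision(seg.pA) == pytest.approx(
                    tp_a / (tp_a + fp_a), rel=1e-12
                )
            tp_b, fp_b = tp_a + d_tp, fp_a + d_fp
            assert seg.precision(seg.pB) == pytest.approx(
                tp_b / (tp_b + fp_b), rel=1e-12
            )


class TestContinuousAucPr:
    def test_separable_unweighted_is_one(self):
        sample = WeightedSample.from_labels([4.0, 3.0, 1.0, 0.0], [1, 1, 0, 0])
        assert auc_pr_continuous(supporting_points(sample)).auc == pytest.approx(1.0)

    def test_worked_example_matches_quadrature(self, weighted_example):
        pts = supporting_points(weighted_example)
        res = auc_pr_continuous(pts)
        assert res.auc == pytest.approx(simpson_auc_pr(pts), abs=1e-9)
        assert res.n_segments == 6

    def test_soft_weights_cap_auc_below_one(self):
        # a point carrying mass in both classes makes precision 1 unreachable
        sample = WeightedSample(
            np.array([3.0, 2.0, 1.0]),
            np.array([1.0, 0.5, 0.0]),
            np.array([0.0, 0.5, 1.0]),
        )
        assert auc_pr_continuous(supporting_points(sample)).auc < 1.0

    def test_equal_tp_pairs_contribute_zero(self):
        # background-only points between two thresholds: vertical PR drop
        sample = WeightedSample.from_labels([5.0, 4.0, 3.0, 2.0], [1, 0, 0, 1])
        res = auc_pr_continuous(supporting_points(sample))
        assert res.n_segments == 2
        pts = supporting_points(sample)
        assert res.auc == pytest.approx(simpson_auc_pr(pts), abs=1e-9)

    def test_single_tied_score_is_class_ratio(self):
        sample = WeightedSample.from_labels(np.zeros(10), [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert auc_pr_continuous(supporting_points(sample)).auc == pytest.approx(0.2)


class TestDiscreteInterpolations:
    def test_perfectly_separated_gives_one(self):
        sample = WeightedSample.from_labels([4.0, 3.0, 1.0, 0.0], [1, 1, 0, 0])
        pts = supporting_points(sample)
        assert auc_pr_discrete_tp(pts).auc == pytest.approx(1.0)
        assert auc_pr_discrete_fp(pts).auc == pytest.approx(1.0)

    def test_constant_precision_curve_all_methods_agree(self):
        # equal tp/fp ratio at every threshold: horizontal curve at 0.5,
        # so the discrete and continuous interpolations coincide exactly
        sample = WeightedSample.from_labels([2.0, 2.0, 1.0, 1.0], [1, 0, 1, 0])
        pts = supporting_points(sample)
        assert auc_pr_discrete_tp(pts).auc == pytest.approx(0.5)
        assert auc_pr_discrete_fp(pts).auc == pytest.approx(0.5)
        assert auc_pr_continuous(pts).auc == pytest.approx(0.5)
        # the upper piece alone: hand trapezoid over precision 0.5 from
        # recall 0.5 to 1 gives 0.25, matching the closed form
        assert segment_auc(cm(2, 2, 2, 2), cm(1, 1, 2, 2), 2.0) == pytest.approx(0.25)

    def test_weighted_data_refused(self, weighted_example):
        pts = supporting_points(weighted_example)
        with pytest.raises(InputError, match="undefined for weighted"):
            auc_pr_discrete_tp(pts)
        with pytest.raises(InputError, match="undefined for weighted"):
            auc_pr_discrete_fp(pts)

    def test_fine_grained_side_close_to_continuous(self):
        # one coarse step in tp (5) against many in fp (295): the fp-stepped
        # interpolation nearly matches the exact integral
        labels = [1] * 5 + [0] * 295 + [1] * 5
        scores = np.concatenate(
            [np.full(5, 3.0), np.linspace(2.0, 1.0, 295), np.full(5, 0.0)]
        )
        sample = WeightedSample.from_labels(scores, labels)
        pts = supporting_points(sample)
        cont = auc_pr_continuous(pts).auc
        dfp = auc_pr_discrete_fp(pts).auc
        assert abs(dfp - cont) < 1e-3

    def test_vertical_fp_segment_no_division_error(self):
        # adjacent thresholds adding only false positives
        sample = WeightedSample.from_labels([3.0, 2.0, 1.0], [1, 0, 1])
        pts = supporting_points(sample)
        assert 0.0 <= auc_pr_discrete_fp(pts).auc <= 1.0

    def test_large_sample_discrete_tp_converges(self):
        rng = np.random.default_rng(11)
        n_fg, n_bg = 500, 5000
        scores = np.concatenate(
            [rng.normal(1.0, 1.0, n_fg), rng.normal(0.0, 1.0, n_bg)]
        )
        labels = np.concatenate([np.ones(n_fg, int), np.zeros(n_bg, int)])
        pts = supporting_points(WeightedSample.from_labels(scores, labels))
        assert abs(auc_pr_discrete_tp(pts).auc - auc_pr_continuous(pts).auc) < 0.005

    def test_convergence_with_sample_size(self):
        """Median |discrete-TP - continuous| shrinks as the sample grows."""
        rng = np.random.default_rng(3)
        medians = []
        for n_fg in (10, 100, 1000):
            diffs = []
            for _ in range(100):
                scores = np.concatenate(
                    [rng.normal(1.28, 1.0, n_fg), rng.normal(0.0, 1.0, 10 * n_fg)]
                )
                labels = np.concatenate(
                    [np.ones(n_fg, int), np.zeros(10 * n_fg, int)]
                )
                pts = supporting_points(WeightedSample.from_labels(scores, labels))
                diffs.append(
                    abs(auc_pr_discrete_tp(pts).auc - auc_pr_continuous(pts).auc)
                )
            medians.append(float(np.median(diffs)))
        assert medians[0] > medians[1] > medians[2]


class TestContainment:
    def test_discrete_intermediates_lie_on_continuous_curve(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = 1
        sample = WeightedSample.from_labels(scores, labels)
        pts = supporting_points(sample)
        # continuous precision at an intermediate recall: hyperbola of the
        # enclosing tp-increasing supporting-point pair
        from softpr.interpolate import _make_segment

        def continuous_precision(recall):
            tp = recall * pts.r_fg
            i = int(np.searchsorted(pts.tp, tp, side="left"))
            seg = _make_segment(
                pts.tp[i - 1], pts.fp[i - 1], pts.tp[i], pts.fp[i], pts.r_fg
            )
            return float(seg.precision(recall))

        support_recalls = pts.tp / pts.r_fg
        for result in (auc_pr_discrete_tp(pts), auc_pr_discrete_fp(pts)):
            for recall, precision in result.points:
                if np.any(np.abs(support_recalls - recall) < 1e-9):
                    continue  # endpoints; only intermediates are claimed
                assert precision == pytest.approx(
                    continuous_precision(recall), abs=1e-12
                ), result.method

    def test_dense_curve_contains_supporting_points(self, unweighted_example):
        pts = supporting_points(unweighted_example)
        dense = dense_pr_curve(pts, per_segment=7)
        support = {
            (round(tp / pts.r_fg, 12), round(tp / (tp + fp), 12))
            for tp, fp in zip(pts.tp, pts.fp)
            if tp + fp > 0
        }
        dense_set = {(round(x, 12), round(y, 12)) for x, y in dense}
        assert support <= dense_set

    def test_per_segment_one_gives_supporting_points_only(self, unweighted_example):
        pts = supporting_points(unweighted_example)
        dense = dense_pr_curve(pts, per_segment=1)
        assert len(dense) == len(pts) - 1


class TestAucRoc:
    def test_separable_is_one(self):
        sample = WeightedSample.from_labels([4.0, 3.0, 1.0, 0.0], [1, 1, 0, 0])
        assert auc_roc(supporting_points(sample)).auc == pytest.approx(1.0)

    def test_all_tied_is_half(self):
        sample = WeightedSample.from_labels(np.zeros(6), [1, 0, 1, 0, 0, 0])
        assert auc_roc(supporting_points(sample)).auc == pytest.approx(0.5)

    def test_rank_statistic_oracle_unweighted(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 150)
        labels[0] = 1
        labels[1] = 0
        scores = np.round(rng.normal(size=150) + labels, 1)  # induce ties
        sample = WeightedSample.from_labels(scores, labels)
        got = auc_roc(supporting_points(sample)).auc
        assert got == pytest.approx(pairwise_auc_roc(sample), abs=1e-12)

    def test_rank_statistic_oracle_weighted(self):
        rng = np.random.default_rng(10)
        w_fg = rng.uniform(0, 1, 80)
        sample = WeightedSample(rng.normal(size=80), w_fg, 1 - w_fg)
        got = auc_roc(supporting_points(sample)).auc
        assert got == pytest.approx(pairwise_auc_roc(sample), abs=1e-12)

    def test_sklearn_agreement(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, 300)
        labels[:2] = [0, 1]
        scores = rng.normal(size=300) + 0.8 * labels
        got = auc_roc(
            supporting_points(WeightedSample.from_labels(scores, labels))
        ).auc
        assert got == pytest.approx(
            float(sklearn.roc_auc_score(labels, scores)), abs=1e-12
        )

    def test_no_background_errors(self):
        sample = WeightedSample(np.array([1.0, 2.0]), np.ones(2), np.zeros(2))
        with pytest.raises(InputError, match="background"):
            auc_roc(supporting_points(sample))


class TestWeightedUnweightedSpecialization:
    def test_hard_weights_equal_count_path(self):
        """0/1-weighted evaluation equals direct integer counting."""
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 100)
        labels[0] = 1
        scores = rng.normal(size=100)
        sample = WeightedSample.from_labels(scores, labels)
        pts = supporting_points(sample)
        assert np.all(pts.tp == np.round(pts.tp))
        assert np.all(pts.fp == np.round(pts.fp))
        # independent integer-count path
        order = np.argsort(-scores, kind="stable")
        tp_count = np.concatenate(([0], np.cumsum(labels[order] == 1)))
        fp_count = np.concatenate(([0], np.cumsum(labels[order] == 0)))
        np.testing.assert_array_equal(pts.tp, tp_count.astype(float))
        np.testing.assert_array_equal(pts.fp, fp_count.astype(float))
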