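"""Greedy point matching and the detection / localisation metrics."""

import numpy as np
import pytest

from suturepoint.codec import PointSet
from suturepoint.matching import (MatchResult, MetricsReport, aggregate_folds,
                                  close_gt_mask, close_subset_analysis,
                                  detection_metrics, match_points,
                                  radius_sweep, rmse_localisation,
                                  summarise_rmse)


def ps(coords, h=100, w=100):
    return PointSet(np.array(coords, dtype=float).reshape(-1, 2), h, w)


def brute_force_greedy(pred, gt, radius):
    """Independent re-enumeration of the greedy matching rule."""
    cands = sorted(
        (float(np.linalg.norm(p - g)), i, j)
        for i, p in enumerate(pred.points)
        for j, g in enumerate(gt.points)
        if np.linalg.norm(p - g) < radius)
    used_p, used_g, pairs = set(), set(), []
    for d, i, j in cands:
        if i not in used_p and j not in used_g:
            used_p.add(i); used_g.add(j)
            pairs.append((i, j))
    return pairs


def max_cardinality_matching(pred, gt, radius):
    """Maximum bipartite matching size within the radius (scipy oracle)."""
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    if not len(pred) or not len(gt):
        return 0
    ok = cdist(pred.points, gt.points) < radius
    cost = np.where(ok, 0.0, 1.0)
    ri, ci = linear_sum_assignment(cost)
    return int(ok[ri, ci].sum())


class TestMatchPoints:
    def test_identical_sets_all_matched(self):
        pts = ps([[1, 1], [5, 5], [9, 2]])
        res = match_points(pts, pts)
        assert (res.tp, res.fp, res.fn) == (3, 0, 0)

    def test_empty_predictions(self):
        res = match_points(ps([]), ps(np.arange(14).reshape(7, 2)))
        assert (res.tp, res.fp, res.fn) == (0, 0, 7)
        res = match_points(ps([[1, 1]]), ps([]))
        assert (res.tp, res.fp, res.fn) == (0, 1, 0)

    def test_second_best_reassignment(self):
        """The closest pair wins; the displaced prediction takes its second-best."""
        gt = ps([[0, 0], [0, 5]])
        pred = ps([[0, 1], [0, 2]])
        res = match_points(pred, gt, radius=6.0)
        assert res.tp == 2
        matched = {(p, g) for p, g, _ in res.pairs}
        assert matched == {(0, 0), (1, 1)}

    def test_strictly_less_than_radius(self):
        res = match_points(ps([[0, 6]]), ps([[0, 0]]), radius=6.0)
        assert res.tp == 0
        res = match_points(ps([[0, 5.999]]), ps([[0, 0]]), radius=6.0)
        assert res.tp == 1

    def test_agrees_with_brute_force_on_seeded_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pred = ps(rng.uniform(0, 40, size=(rng.integers(0, 11), 2)), 40, 40)
            gt = ps(rng.uniform(0, 40, size=(rng.integers(0, 11), 2)), 40, 40)
            res = match_points(pred, gt, 6.0)
            expected = brute_force_greedy(pred, gt, 6.0)
            assert res.tp == len(expected)
            assert {(p, g) for p, g, _ in res.pairs} == set(expected)
            assert res.tp + res.fp == len(pred)
            assert res.tp + res.fn == len(gt)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(77)
        pred = ps(rng.uniform(0, 50, size=(8, 2)))
        gt = ps(rng.uniform(0, 50, size=(7, 2)))
        base = match_points(pred, gt, 8.0)
        perm_p = rng.permutation(len(pred))
        perm_g = rng.permutation(len(gt))
        shuffled = match_points(ps(pred.points[perm_p]), ps(gt.points[perm_g]), 8.0)
        assert (base.tp, base.fp, base.fn) == (shuffled.tp, shuffled.fp, shuffled.fn)
        base_pairs = {(tuple(pred.points[p]), tuple(gt.points[g]))
                      for p, g, _ in base.pairs}
        shuf_pairs = {(tuple(pred.points[perm_p][p]), tuple(gt.points[perm_g][g]))
                      for p, g, _ in shuffled.pairs}
        assert base_pairs == shuf_pairs

    def test_greedy_optimal_in_separation_regime(self):
        """Greedy equals maximum matching when distances avoid [r/2, r]."""
        radius = 6.0
        checked = 0
        for seed in range(400):
            rng = np.random.default_rng(1000 + seed)
            pred = ps(rng.uniform(0, 30, size=(rng.integers(1, 7), 2)), 30, 30)
            gt = ps(rng.uniform(0, 30, size=(rng.integers(1, 7), 2)), 30, 30)
            from scipy.spatial.distance import cdist
            d = cdist(pred.points, gt.points)
            if np.any((d >= radius / 2) & (d <= radius)):
                continue
            checked += 1
            assert match_points(pred, gt, radius).tp == \
                max_cardinality_matching(pred, gt, radius)
        assert checked >= 20

    def test_tp_nondecreasing_in_radius(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pred = ps(rng.uniform(0, 60, size=(10, 2)))
            gt = ps(rng.uniform(0, 60, size=(10, 2)))
            tps = [match_points(pred, gt, r).tp for r in (6.0, 8.0, 10.0)]
            assert tps[0] <= tps[1] <= tps[2]


class TestDetectionMetrics:
    def test_equal_counts_give_fifty_percent(self):
        rep = detection_metrics([MatchResult((), 2, 2, 2, 6.0)])
        assert (rep.ppv, rep.tpr, rep.f1) == (50.0, 50.0, 0.5)

    def test_worked_example(self):
        rep = detection_metrics([MatchResult((), 3, 1, 5, 6.0)])
        assert rep.ppv == 75.0
        assert rep.tpr == 37.5
        assert rep.f1 == pytest.approx(0.5)

    def test_no_true_positives_gives_zero_f1(self):
        rep = detection_metrics([MatchResult((), 0, 4, 3, 6.0),
                                 MatchResult((), 0, 0, 0, 6.0)])
        assert rep.f1 == 0.0

    def test_f1_equals_ppv_fraction_when_ppv_equals_tpr(self):
        rep = detection_metrics([MatchResult((), 3, 2, 2, 6.0)])
        assert rep.ppv == rep.tpr
        assert rep.f1 == pytest.approx(rep.ppv / 100.0)

    def test_pooled_vs_per_image(self):
        results = [MatchResult((), 4, 0, 0, 6.0), MatchResult((), 0, 2, 2, 6.0)]
        pooled = detection_metrics(results, "pooled")
        per_image = detection_metrics(results, "per_image")
        assert pooled.ppv == pytest.approx(100.0 * 4 / 6)
        assert per_image.ppv == pytest.approx(50.0)  # mean of 100% and 0%

    def test_mixed_radii_rejected(self):
        with pytest.raises(ValueError):
            detection_metrics([MatchResult((), 1, 0, 0, 6.0),
                               MatchResult((), 1, 0, 0, 8.0)])


class TestRmse:
    def test_perfect_predictions(self):
        pts = ps([[3, 4], [10, 10]])
        assert rmse_localisation(pts, pts) == 0.0

    def test_constant_displacement(self):
        gt = ps([[10, 10], [30, 30]])
        pred = ps([[10, 13], [30, 33]])
        assert rmse_localisation(pred, gt) == pytest.approx(3.0)

    def test_worked_example(self):
        got = rmse_localisation(ps([[0, 3], [4, 0]]), ps([[0, 0]]))
        assert got == pytest.approx(np.sqrt(12.5), abs=1e-9)

    def test_no_prediction_marker_and_summary(self):
        gt = ps([[5, 5]])
        assert rmse_localisation(ps([]), gt) is None
        report = summarise_rmse([3.0, None, 5.0])
        assert report.rmse == pytest.approx(4.0)
        assert report.n_images_scored == 2
        assert report.n_images_total == 3

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            rmse_localisation(ps([[1, 1]]), ps([]))

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        pred = ps(rng.uniform(0, 50, (6, 2)))
        gt = ps(rng.uniform(0, 50, (4, 2)))
        a = rmse_localisation(pred, gt)
        b = rmse_localisation(ps(pred.points[::-1]), gt)
        assert a == pytest.approx(b)


class TestCloseSubset:
    def test_all_far_apart(self):
        gt = ps([[0, 0], [0, 30], [60, 0]])
        assert not close_gt_mask(gt, 15.0).any()
        res = match_points(gt, gt, 6.0)
        df = close_subset_analysis(gt, res, res)
        non_close = df[df.subset == "non_close"]
        assert (non_close.tp_percent == 100.0).all()
        assert (df[df.subset == "close"].n_points == 0).all()

    def test_pair_at_ten_pixels_is_close(self):
        gt = ps([[0, 0], [0, 10]])
        assert close_gt_mask(gt, 15.0).all()

    def test_worked_percentages(self):
        # 4 close points (two pairs), 6 far points; model a matches 3 close
        # and 5 non-close
        close_pts = [[0, 0], [0, 10], [50, 0], [50, 10]]
        far_pts = [[0, 40], [20, 40], [40, 40], [60, 40], [80, 40], [80, 0]]
        gt = ps(close_pts + far_pts)
        pred = ps(close_pts[:3] + far_pts[:5])  # misses one of each subset
        res = match_points(pred, gt, 6.0)
        other = match_points(gt, gt, 6.0)
        df = close_subset_analysis(gt, res, other)
        a = df[df.model == "a"].set_index("subset").tp_percent
        assert a["close"] == pytest.approx(75.0)
        assert a["non_close"] == pytest.approx(100.0 * 5 / 6)

    def test_mismatched_gt_rejected(self):
        gt = ps([[0, 0], [0, 30]])
        res = match_points(gt, gt, 6.0)
        bad = match_points(ps([[0, 0]]), ps([[0, 0]]), 6.0)
        with pytest.raises(ValueError):
            close_subset_analysis(gt, res, bad)


class TestRadiusSweepAndFolds:
    def test_perfect_predictions_at_all_radii(self):
        sets = [ps([[10, 10], [20, 30]]), ps([[5, 5]])]
        df = radius_sweep(sets, sets)
        assert (df.f1 == 1.0).all()
        assert list(df.radius) == [6.0, 8.0, 10.0]

    def test_displacement_crosses_threshold(self):
        gt = ps([[20, 20], [40, 40]])
        pred = ps([[20, 27], [40, 47]])  # displaced by exactly 7 px
        df = radius_sweep([pred], [gt]).set_index("radius")
        assert df.loc[6.0].tpr == 0.0
        assert df.loc[8.0].tpr == 100.0
        assert df.loc[10.0].tpr == 100.0

    def test_descending_radii_rejected(self):
        with pytest.raises(ValueError):
            radius_sweep([], [], radii=[10.0, 6.0])

    def test_aggregate_folds(self):
        reports = [MetricsReport(60.0, 40.0, 0.4, 6.0, 10),
                   MetricsReport(80.0, 60.0, 0.6, 6.0, 10)]
        df = aggregate_folds(reports).set_index("metric")
        assert df.loc["f1", "mean"] == pytest.approx(0.5)
        assert df.loc["ppv", "mean"] == pytest.approx(70.0)
        assert df.loc["ppv", "std"] == pytest.approx(10.0)
        identical = aggregate_folds([reports[0], reports[0]])
        assert (identical["std"] == 0.0).all()
        with pytest.raises(ValueError):
            aggregate_folds([reports[0]])


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def point_sets(draw, max_points=8, size=40.0):
    n = draw(st.integers(0, max_points))
    coords = draw(st.lists(
        st.tuples(st.floats(0.0, size - 1), st.floats(0.0, size - 1)),
        min_size=n, max_size=n))
    return ps(coords, int(size), int(size))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(pred=point_sets(), gt=point_sets(), radius=st.floats(1.0, 12.0))
def test_match_counts_conserved_for_any_inputs(pred, gt, radius):
    """tp+fp == |pred| and tp+fn == |gt| hold for arbitrary point sets."""
    res = match_points(pred, gt, radius)
    assert res.tp + res.fp == len(pred)
    assert res.tp + res.fn == len(gt)
    assert all(d < radius for _, _, d in res.pairs)
    matched_preds = [p for p, _, _ in res.pairs]
    matched_gts = [g for _, g, _ in res.pairs]
    assert len(set(matched_preds)) == len(matched_preds)
    assert len(set(matched_gts)) == len(matched_gts)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(gt=point_sets(max_points=6), pred=point_sets(max_points=6))
def test_rmse_defined_iff_predictions_exist(gt, pred):
    """The localisation RMSE is a non-negative number exactly when there are
    predictions (and ground truth is nonempty)."""
    if len(gt) == 0:
        with pytest.raises(ValueError):
            rmse_localisation(pred, gt)
    elif len(pred) == 0:
        assert rmse_localisation(pred, gt) is None
    else:
        value = rmse_localisation(pred, gt)
        assert value >= 0.0
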