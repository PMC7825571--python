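"""Tracker: cost terms, padded cost matrix, Hungarian assignment, track IDs."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mothtrap.segmentation import Detection
from mothtrap.tracking import (
    CostParams,
    Tracker,
    area_cost,
    build_cost_matrix,
    dist,
    max_dist,
    pair_cost,
    solve_assignment,
    step_tracks,
)


def det(frame, cx, cy, w=100, h=100, area=None):
    return Detection(frame, (int(cx - w / 2), int(cy - h / 2), w, h), (cx, cy),
                     area if area is not None else w * h * 0.7)


def brute_force_assignment(cost):
    """Minimum-cost perfect matching by enumerating all permutations."""
    n = cost.shape[0]
    best, best_perm = math.inf, None
    for perm in itertools.permutations(range(n)):
        total = sum(cost[i, perm[i]] for i in range(n))
        if total < best:
            best, best_perm = total, perm
    return best, best_perm


class TestCostTerms:
    @pytest.mark.parametrize("p1,p2,expected", [
        ((0, 0), (3, 4), 5.0),
        ((7, 7), (7, 7), 0.0),
        ((100, 200), (400, 600), 500.0),
    ])
    def test_euclidean_distance(self, p1, p2, expected):
        assert dist(p1, p2) == pytest.approx(expected)

    def test_max_dist_is_the_image_diagonal(self):
        assert max_dist(3, 4) == pytest.approx(5.0)
        assert max_dist(2160, 3840) == pytest.approx((2160 ** 2 + 3840 ** 2) ** 0.5)

    def test_max_dist_monotone_and_guarded(self):
        assert max_dist(2160, 3841) > max_dist(2160, 3840) < max_dist(2161, 3840)
        with pytest.raises(ValueError):
            max_dist(0, 100)

    @pytest.mark.parametrize("a,b,expected", [
        (100, 100, 1.0), (50, 100, 0.5), (100, 50, 0.5),
    ])
    def test_area_cost_min_over_max(self, a, b, expected):
        assert area_cost(a, b) == pytest.approx(expected)

    def test_area_cost_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            area_cost(0, 10)


class TestPairCost:
    def test_zero_iff_identical_position_and_size(self):
        d = det(0, 500, 500)
        assert pair_cost(d, det(1, 500, 500), CostParams(), 1080, 1920) == 0.0

    def test_maximal_distance_with_equal_areas(self):
        # cost reduces to Wdist when dist == diagonal and areas match
        params = CostParams(w_dist=0.8, w_area=0.2)
        a = det(0, 50, 50)
        b = det(1, 50 + 1920, 50 + 1080)
        assert pair_cost(a, b, params, 1080, 1920) == pytest.approx(0.8)

    def test_area_mismatch_alone(self):
        params = CostParams(w_dist=0.8, w_area=0.2)
        a = det(0, 500, 500, w=100, h=100)
        b = det(1, 500, 500, w=100, h=50)
        assert pair_cost(a, b, params, 1080, 1920) == pytest.approx(0.1)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        params = CostParams()
        for _ in range(50):
            a = det(0, rng.uniform(100, 1800), rng.uniform(100, 900),
                    w=int(rng.integers(50, 400)), h=int(rng.integers(50, 400)))
            b = det(1, rng.uniform(100, 1800), rng.uniform(100, 900),
                    w=int(rng.integers(50, 400)), h=int(rng.integers(50, 400)))
            cab = pair_cost(a, b, params, 1080, 1920)
            assert cab == pytest.approx(pair_cost(b, a, params, 1080, 1920))
            assert 0 <= cab <= params.w_dist + params.w_area


class TestCostMatrix:
    def test_dummy_row_pads_rectangular_problem(self):
        params = CostParams()
        prev = [det(0, 100, 100), det(0, 500, 500)]
        curr = [det(1, 100, 100), det(1, 500, 500), det(1, 900, 300)]
        cost = build_cost_matrix(prev, curr, params, 1080, 1920)
        assert cost.shape == (3, 3)
        assert np.all(cost[2, :] == params.dummy_cost)
        assert np.all(cost[:2, :] <= params.dummy_cost)
        assert np.isfinite(cost).all()

    def test_identical_singletons_give_zero_matrix(self):
        d = det(0, 300, 300)
        cost = build_cost_matrix([d], [det(1, 300, 300)], CostParams(), 1080, 1920)
        assert cost.shape == (1, 1) and cost[0, 0] == 0.0

    def test_dummy_cost_must_exceed_real_costs(self):
        with pytest.raises(ValueError):
            CostParams(w_dist=0.8, w_area=0.2, dummy_cost=0.5)


class TestSolveAssignment:
    def test_two_by_two_prefers_global_minimum(self):
        # greedy would take the 1 then pay 4; optimal total is 4 via the anti-diagonal
        result = solve_assignment(np.array([[1.0, 2.0], [2.0, 4.0]]))
        assert result.total_cost == pytest.approx(4.0)
        assert sorted(result.matches) == [(0, 1), (1, 0)]

    def test_zero_matrix_any_permutation(self):
        result = solve_assignment(np.zeros((4, 4)))
        assert result.total_cost == 0.0
        assert len(result.matches) == 4

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            solve_assignment(np.zeros((2, 3)))

    @settings(max_examples=120, deadline=None)
    @given(st.integers(2, 7), st.integers(0, 2 ** 32 - 1))
    def test_equals_brute_force_on_random_matrices(self, n, seed):
        cost = np.random.default_rng(seed).uniform(0, 10, (n, n))
        result = solve_assignment(cost)
        best, _ = brute_force_assignment(cost)
        assert result.total_cost == pytest.approx(best)

    def test_dummy_matches_reported_as_entries_and_exits(self):
        params = CostParams()
        prev = [det(0, 100, 100)]
        curr = [det(1, 100, 100), det(1, 1500, 800)]
        cost = build_cost_matrix(prev, curr, params, 1080, 1920)
        result = solve_assignment(cost, n_prev=1, n_curr=2)
        assert result.matches == [(0, 0)]
        assert result.entered == [1]
        assert result.exited == []


class TestStepTracks:
    def test_stationary_detections_keep_their_ids(self):
        params = CostParams()
        dets0 = [det(0, 200, 200), det(0, 900, 500)]
        active, closed, next_id = step_tracks([], dets0, params, 1080, 1920, 0)
        ids0 = {t.track_id for t in active}
        dets1 = [det(1, 200, 200), det(1, 900, 500)]
        active, closed, next_id = step_tracks(active, dets1, params, 1080, 1920, next_id)
        assert {t.track_id for t in active} == ids0
        assert closed == [] and next_id == 2

    def test_far_new_detection_opens_exactly_one_track(self):
        params = CostParams()
        active, _, next_id = step_tracks([], [det(0, 200, 200)], params, 1080, 1920, 0)
        active, closed, next_id = step_tracks(
            active, [det(1, 200, 200), det(1, 1700, 900)], params, 1080, 1920, next_id)
        assert len(active) == 2 and next_id == 2 and not closed

    def test_vanished_detection_closes_its_track(self):
        params = CostParams()
        active, _, next_id = step_tracks(
            [], [det(0, 200, 200), det(0, 900, 500)], params, 1080, 1920, 0)
        active, closed, next_id = step_tracks(active, [det(1, 200, 200)],
                                              params, 1080, 1920, next_id)
        assert len(active) == 1 and len(closed) == 1
        assert closed[0].last.centroid == (900, 500)

    def test_no_duplicate_ids_within_a_frame(self):
        rng = np.random.default_rng(5)
        tracker = Tracker(1080, 1920)
        for f in range(10):
            dets = [det(f, rng.uniform(100, 1800), rng.uniform(100, 900))
                    for _ in range(rng.integers(0, 6))]
            active = tracker.update(dets)
            ids = [t.track_id for t in active]
            assert len(ids) == len(set(ids))

    def test_id_conservation_on_stationary_scene(self):
        tracker = Tracker(1080, 1920)
        points = [(200, 200), (900, 500), (1600, 800)]
        for f in range(20):
            tracker.update([det(f, x + 0.5 * np.sin(f), y) for x, y in points])
        tracks = tracker.finish()
        assert len(tracks) == 3
        assert all(len(t.detections) == 20 for t in tracks)
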