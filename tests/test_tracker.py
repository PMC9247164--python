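"""Geometric costs, gated Hungarian assignment, and track lifecycle."""

import math

import numpy as np
import pytest

from conftest import brute_force_assignment
from polypcadx.datamodel import (
    BoundingBox,
    CharacterizationOutput,
    Detection,
    FrameRecord,
    LightMode,
)
from polypcadx.tracker import (
    Tracker,
    TrackerParams,
    cosine_distance,
    iou,
    solve_assignment,
)


class TestIoU:
    def test_identical(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 30, 30)) == 0.0

    def test_half_overlap(self):
        a = BoundingBox(0, 0, 10, 10)
        b = BoundingBox(5, 0, 15, 10)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 50, size=(2, 2))
            y = rng.uniform(0, 50, size=(2, 2))
            a = BoundingBox(x[0, 0], x[1, 0], x[0, 0] + 1 + x[0, 1], x[1, 0] + 1 + x[1, 1])
            b = BoundingBox(y[0, 0], y[1, 0], y[0, 0] + 1 + y[0, 1], y[1, 0] + 1 + y[1, 1])
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0


class TestCosineDistance:
    def test_identical_direction(self):
        v = np.array([2.0, 1.0, 0.5])
        assert cosine_distance(v, 3 * v) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 1.0

    def test_closed_form(self):
        d = cosine_distance(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        assert d == pytest.approx(1 - 1 / math.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(3), np.ones(3))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.ones(3), np.ones(4))


class TestSolveAssignment:
    def test_prefers_global_minimum(self):
        res = solve_assignment(np.array([[1.0, 2.0], [2.0, 4.0]]), gate=np.inf)
        assert set(res.pairs) == {(0, 1), (1, 0)}
        assert sum(res.costs) == pytest.approx(4.0)

    def test_gate_excludes(self):
        res = solve_assignment(np.array([[0.2]]), gate=0.1)
        assert res.pairs == ()
        assert res.unmatched_rows == (0,) and res.unmatched_cols == (0,)

    def test_empty(self):
        res = solve_assignment(np.zeros((0, 3)), gate=1.0)
        assert res.pairs == () and res.unmatched_cols == (0, 1, 2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            m, n = rng.integers(1, 5, size=2)
            cost = rng.uniform(0, 1, size=(m, n))
            gate = rng.uniform(0.2, 1.2)
            res = solve_assignment(cost, gate)
            card, total = brute_force_assignment(cost, gate)
            assert len(res.pairs) == card
            assert sum(res.costs) == pytest.approx(total)


def _frame(index, boxes, descriptors, mode=LightMode.WL, score=0.8, quality=2):
    dets = [
        Detection(index, box, CharacterizationOutput(score, d, quality))
        for box, d in zip(boxes, descriptors)
    ]
    return FrameRecord(index, mode, 1000, 1000, dets)


E1 = np.array([1.0, 0.0, 0.0, 0.0])
E2 = np.array([0.0, 1.0, 0.0, 0.0])


class TestTrackerLifecycle:
    def test_spatial_match_extends_history(self):
        tracker = Tracker(TrackerParams(tau_iou=0.3))
        tracker.step(_frame(0, [BoundingBox(100, 100, 200, 200)], [E1]))
        log = tracker.step(_frame(1, [BoundingBox(110, 100, 210, 200)], [E1]))
        assert log == [(0, 0, "spatial", pytest.approx(1 - iou(
            BoundingBox(100, 100, 200, 200), BoundingBox(110, 100, 210, 200))))]
        assert len(tracker.tracks) == 1
        assert tracker.tracks[0].frame_indices == [0, 1]

    def test_appearance_reidentification_after_jump(self):
        tracker = Tracker(TrackerParams(tau_iou=0.3, tau_app=0.2))
        tracker.step(_frame(0, [BoundingBox(0, 0, 100, 100)], [E1]))
        # far jump: IoU 0, but nearly identical descriptor
        near = E1 + np.array([0.0, 0.05, 0.0, 0.0])
        log = tracker.step(_frame(1, [BoundingBox(700, 700, 800, 800)], [near]))
        assert log[0][1] == 0 and log[0][2] == "appearance"
        assert len(tracker.tracks) == 1

    def test_retired_track_not_revived(self):
        params = TrackerParams(max_missed=2)
        tracker = Tracker(params)
        box = BoundingBox(0, 0, 100, 100)
        tracker.step(_frame(0, [box], [E1]))
        for t in range(1, params.max_missed + 2):
            tracker.step(_frame(t, [], []))
        assert not tracker.tracks[0].active
        log = tracker.step(_frame(10, [box], [E1]))
        assert log[0][2] == "new" and log[0][1] == 1  # fresh id, never reused

    def test_simultaneous_polyps_get_distinct_tracks(self):
        tracker = Tracker()
        b1, b2 = BoundingBox(0, 0, 100, 100), BoundingBox(500, 500, 620, 620)
        for t in range(5):
            tracker.step(_frame(t, [b1, b2], [E1, E2]))
        active = tracker.active_tracks
        assert len(active) == 2
        assert set(active[0].frame_indices) == set(range(5))
        assert set(active[1].frame_indices) == set(range(5))

    def test_missing_descriptor_rejected(self):
        tracker = Tracker()
        frame = FrameRecord(0, LightMode.WL, 100, 100,
                            [Detection(0, BoundingBox(0, 0, 10, 10), None)])
        with pytest.raises(ValueError, match="characterization"):
            tracker.step(frame)
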