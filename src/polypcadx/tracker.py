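"""Online polyp re-identification (tracking by detection).

Each frame's detections are associated to the set of actively followed
polyps in two passes, both solved as unbalanced linear assignment problems
with the Hungarian algorithm:

1. a spatial pass with cost ``1 - IoU(detection, track's last box)`` and
   gate ``1 - tau_iou`` (i.e. a match requires IoU >= tau_iou);
2. an appearance pass on the leftovers of the spatial pass, with cosine
   distance between descriptors as cost and gate ``tau_app`` — this is what
   re-identifies a polyp after a jump across the frame.

Detections unmatched after both passes open new tracks; tracks unmatched
for more than ``max_missed`` consecutive frames are retired and never
revived (a reappearing polyp becomes a new track).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datamodel import BoundingBox, FrameRecord, TrackedPolyp

__all__ = [
    "TrackerParams",
    "AssignmentResult",
    "iou",
    "cosine_distance",
    "solve_assignment",
    "Tracker",
]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - cos(u, v)``, in [0, 2]. Zero vectors have no direction and
    raise a ValueError."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"descriptor dimensions differ: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - float(u @ v) / (nu * nv))


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of one gated assignment pass.

    ``pairs`` maps detection index -> track id (the stage's column label);
    matched and unmatched sets partition both sides."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_rows: tuple[int, ...]
    unmatched_cols: tuple[int, ...]
    stage: str  # "spatial" | "appearance"
    costs: tuple[float, ...] = ()


def solve_assignment(
    cost: np.ndarray, gate: float, stage: str = "spatial", col_ids: list[int] | None = None
) -> AssignmentResult:
    """Minimal-cost bipartite matching with a gate.

    Among matchings that use only admissible pairs (``cost <= gate``), a
    maximum-cardinality one of minimal total cost is returned. Implemented
    by substituting inadmissible entries with a constant larger than the sum
    of all admissible costs and solving the rectangular problem with the
    Hungarian algorithm, then discarding gated pairs.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    m, n = cost.shape
    ids = list(range(n)) if col_ids is None else list(col_ids)
    if m == 0 or n == 0:
        return AssignmentResult(
            (), tuple(range(m)), tuple(ids), stage
        )
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost entries must be finite")
    admissible = cost <= gate
    big = float(np.sum(np.abs(cost[admissible]))) + 1.0 if admissible.any() else 1.0
    padded = np.where(admissible, cost, big)
    rows, cols = linear_sum_assignment(padded)
    pairs = []
    costs = []
    matched_rows: set[int] = set()
    matched_cols: set[int] = set()
    for r, c in zip(rows, cols):
        if admissible[r, c]:
            pairs.append((int(r), ids[int(c)]))
            costs.append(float(cost[r, c]))
            matched_rows.add(int(r))
            matched_cols.add(int(c))
    return AssignmentResult(
        pairs=tuple(pairs),
        unmatched_rows=tuple(r for r in range(m) if r not in matched_rows),
        unmatched_cols=tuple(ids[c] for c in range(n) if c not in matched_cols),
        stage=stage,
        costs=tuple(costs),
    )


@dataclass(frozen=True)
class TrackerParams:
    """Gates and lifecycle parameters (conventional tracking-by-detection
    values; the association logic, not these numbers, is the contract)."""

    tau_iou: float = 0.3     # minimal IoU for a spatial match
    tau_app: float = 0.2     # maximal cosine distance for an appearance match
    max_missed: int = 8      # frames a track may go unseen before retirement
    use_mean_descriptor: bool = False  # appearance cost vs mean of history


@dataclass
class Tracker:
    """Stateful per-clip tracker. Feed frames in order via :meth:`step`."""

    params: TrackerParams = field(default_factory=TrackerParams)
    tracks: list[TrackedPolyp] = field(default_factory=list)
    _next_id: int = 0

    @property
    def active_tracks(self) -> list[TrackedPolyp]:
        return [t for t in self.tracks if t.active]

    def _track_descriptor(self, track: TrackedPolyp) -> np.ndarray:
        if self.params.use_mean_descriptor:
            return np.mean(np.stack(track.descriptors), axis=0)
        return track.last_descriptor

    def step(self, frame: FrameRecord) -> list[tuple[int, int, str, float]]:
        """Assign the frame's detections to tracks.

        Returns the assignment log for the frame: one
        ``(detection_index, track_id, stage, cost)`` row per detection,
        with stage ``"new"`` and cost ``nan`` for detections that opened a
        new track. Every detection receives exactly one track id.
        """
        dets = frame.detections
        for det in dets:
            if det.char is None:
                raise ValueError(
                    f"frame {frame.frame_index}: detection lacks characterization"
                )
        active = self.active_tracks
        log: list[tuple[int, int, str, float]] = []
        assigned: dict[int, tuple[int, str, float]] = {}

        # Stage 1: spatial association against each track's last box.
        if dets and active:
            cost1 = np.array(
                [[1.0 - iou(d.box, t.last_box) for t in active] for d in dets]
            )
            res1 = solve_assignment(
                cost1,
                gate=1.0 - self.params.tau_iou,
                stage="spatial",
                col_ids=[t.track_id for t in active],
            )
        else:
            res1 = AssignmentResult(
                (), tuple(range(len(dets))), tuple(t.track_id for t in active), "spatial"
            )
        for (r, tid), c in zip(res1.pairs, res1.costs):
            assigned[r] = (tid, "spatial", c)

        # Stage 2: appearance association on the leftovers of stage 1.
        rows2 = list(res1.unmatched_rows)
        by_id = {t.track_id: t for t in active}
        cols2 = [by_id[tid] for tid in res1.unmatched_cols]
        if rows2 and cols2:
            cost2 = np.array(
                [
                    [
                        cosine_distance(
                            dets[r].char.descriptor, self._track_descriptor(t)
                        )
                        for t in cols2
                    ]
                    for r in rows2
                ]
            )
            res2 = solve_assignment(
                cost2,
                gate=self.params.tau_app,
                stage="appearance",
                col_ids=[t.track_id for t in cols2],
            )
            for (r2, tid), c in zip(res2.pairs, res2.costs):
                assigned[rows2[r2]] = (tid, "appearance", c)

        # Append matches; open new tracks for still-unmatched detections
        # in detection order (deterministic id allocation).
        matched_ids = set()
        for r in range(len(dets)):
            if r in assigned:
                tid, stage, c = assigned[r]
                track = by_id[tid]
                det = dets[r]
                track.append(
                    frame.frame_index,
                    det.box,
                    det.char.score,
                    det.char.quality,
                    det.char.descriptor,
                    frame.light_mode,
                )
                matched_ids.add(tid)
                log.append((r, tid, stage, c))
            else:
                det = dets[r]
                track = TrackedPolyp(track_id=self._next_id)
                self._next_id += 1
                track.append(
                    frame.frame_index,
                    det.box,
                    det.char.score,
                    det.char.quality,
                    det.char.descriptor,
                    frame.light_mode,
                )
                self.tracks.append(track)
                matched_ids.add(track.track_id)
                log.append((r, track.track_id, "new", float("nan")))

        # Lifecycle: unmatched active tracks age and eventually retire.
        for t in active:
            if t.track_id not in matched_ids:
                t.missed += 1
                if t.missed > self.params.max_missed:
                    t.active = False
        return log
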