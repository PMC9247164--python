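"""End-to-end per-clip pipeline: track, aggregate, decide.

``run_pipeline`` replays a detection stream through the re-identification
tracker and the temporal aggregator and emits, deterministically:

* an assignment log — one row per detection with its track id, the
  assignment stage that bound it (spatial / appearance / new) and the cost;
* a frame-decision log — the live four-state output for every detection's
  track at every frame;
* a per-track, per-illumination-mode clip summary with the three-state call
  and the per-polyp CADx ROC score.

Temporal evidence is aggregated separately per illumination mode: the
white-light decision stream sees only white-light frames and likewise for
blue light, so each mode's clip call is derived from its own frames only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .aggregator import AggregationParams, decide_from_window
from .clip_decision import decide_clip_counts
from .datamodel import FrameRecord, FrameState, LightMode, TrackedPolyp
from .reader_stats import cadx_score
from .tracker import Tracker, TrackerParams

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    assignments: pd.DataFrame      # frame_index, detection_index, track_id, stage, cost
    frame_decisions: pd.DataFrame  # frame_index, track_id, light_mode, state, counts
    clip_summary: pd.DataFrame     # track_id, light_mode, call, counts, cadx_score
    tracks: list[TrackedPolyp] = field(default_factory=list)


def run_pipeline(
    frames: Iterable[FrameRecord],
    tracker_params: TrackerParams | None = None,
    agg_params: AggregationParams | None = None,
) -> PipelineResult:
    """Run tracking + temporal aggregation over one clip's frame records.

    Deterministic given the stream and the parameters; every detection
    receives exactly one track id.
    """
    tracker_params = tracker_params or TrackerParams()
    agg_params = agg_params or AggregationParams()
    tracker = Tracker(params=tracker_params)

    assign_rows: list[tuple] = []
    decision_rows: list[tuple] = []
    # per (track_id, mode): accumulated (score, quality) history in that mode
    mode_hist: dict[tuple[int, str], list[tuple[float, int]]] = {}
    # per (track_id, mode): printed-state counts for the clip rule
    clip_counts: dict[tuple[int, str], list[int]] = {}
    descriptor_dim: int | None = None

    for frame in frames:
        for det in frame.detections:
            if det.char is None:
                raise ValueError(
                    f"frame {frame.frame_index}: detection not characterized"
                )
            if descriptor_dim is None:
                descriptor_dim = det.char.descriptor.size
            elif det.char.descriptor.size != descriptor_dim:
                raise ValueError(
                    f"frame {frame.frame_index}: descriptor dimension "
                    f"{det.char.descriptor.size} != {descriptor_dim}"
                )
        log = tracker.step(frame)
        mode = frame.light_mode.value
        for det_idx, track_id, stage, cost in log:
            assign_rows.append((frame.frame_index, det_idx, track_id, stage, cost))
            det = frame.detections[det_idx]
            key = (track_id, mode)
            hist = mode_hist.setdefault(key, [])
            hist.append((det.char.score, det.char.quality))
            state, n_a, n_na, n_valid = decide_from_window(
                hist[-agg_params.window :], agg_params
            )
            decision_rows.append(
                (frame.frame_index, track_id, mode, state.value, n_a, n_na, n_valid)
            )
            counts = clip_counts.setdefault(key, [0, 0])
            if state is FrameState.ADENOMA:
                counts[0] += 1
            elif state is FrameState.NON_ADENOMA:
                counts[1] += 1

    summary_rows = []
    for (track_id, mode), hist in sorted(mode_hist.items()):
        n_a, n_na = clip_counts[(track_id, mode)]
        call = decide_clip_counts(n_a, n_na)
        score = cadx_score(n_a, n_na)
        summary_rows.append(
            (track_id, mode, call.value, n_a, n_na,
             float("nan") if score is None else score, len(hist))
        )

    assignments = pd.DataFrame(
        assign_rows,
        columns=["frame_index", "detection_index", "track_id", "stage", "cost"],
    )
    frame_decisions = pd.DataFrame(
        decision_rows,
        columns=[
            "frame_index", "track_id", "light_mode", "state",
            "n_adenoma", "n_nonadenoma", "n_valid",
        ],
    )
    clip_summary = pd.DataFrame(
        summary_rows,
        columns=[
            "track_id", "light_mode", "call", "n_adenoma", "n_nonadenoma",
            "cadx_score", "n_frames",
        ],
    )
    return PipelineResult(
        assignments=assignments,
        frame_decisions=frame_decisions,
        clip_summary=clip_summary,
        tracks=tracker.tracks,
    )
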