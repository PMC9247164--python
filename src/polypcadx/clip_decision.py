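"""Clip-level calls and the reviewer-response mapping.

A polyp videoclip receives, per illumination mode, a three-state call
derived from the live per-frame outputs: ``adenoma`` when the number of
frames printed "adenoma" is greater than or equal to the number printed
"non-adenoma" (ties go to adenoma — the clinically conservative direction),
``non_adenoma`` on a strict non-adenoma majority, and ``undetermined`` when
no frame in the clip carried either label. Frames in the ``analysing`` or
``no_prediction`` state contribute to neither count.

Reviewer survey answers are collapsed onto the same three-state space:
"adenoma" or "carcinoma" count as adenoma, "hyperplastic" or "SSL" as
non-adenoma, and "uncertain" as undetermined.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .datamodel import (
    ClipCall,
    ClipDecision,
    Confidence,
    FrameDecision,
    FrameState,
    LightMode,
    RawCall,
)
from .reader_stats import reviewer_score

__all__ = ["decide_clip", "decide_clip_counts", "map_reviewer", "select_target_track"]


def decide_clip_counts(n_adenoma: int, n_nonadenoma: int) -> ClipCall:
    """The clip rule on bare frame counts."""
    if n_adenoma == 0 and n_nonadenoma == 0:
        return ClipCall.UNDETERMINED
    if n_adenoma >= n_nonadenoma:
        return ClipCall.ADENOMA
    return ClipCall.NON_ADENOMA


def decide_clip(
    frame_decisions: Iterable[FrameDecision],
    polyp_id: str,
    light_mode: LightMode,
) -> ClipDecision:
    """Collapse one track's per-frame decisions (already restricted to the
    frames of ``light_mode``) into the clip-level call. Permutation-invariant
    over frame order: only the state counts matter."""
    n_a = n_na = 0
    for fd in frame_decisions:
        if fd.state is FrameState.ADENOMA:
            n_a += 1
        elif fd.state is FrameState.NON_ADENOMA:
            n_na += 1
    return ClipDecision(
        polyp_id=polyp_id,
        light_mode=light_mode,
        call=decide_clip_counts(n_a, n_na),
        n_adenoma=n_a,
        n_nonadenoma=n_na,
    )


def map_reviewer(
    raw_call: RawCall, confidence: Confidence | None
) -> tuple[ClipCall, int | None]:
    """Map a reviewer's (5-class call, 4-level confidence) answer to the
    three-state call plus the eight-level ROC score (None when
    undetermined)."""
    if raw_call is RawCall.UNCERTAIN:
        if confidence is not None:
            raise ValueError("confidence must be absent for an 'uncertain' call")
        return ClipCall.UNDETERMINED, None
    if confidence is None:
        raise ValueError(f"confidence required for call {raw_call.value!r}")
    if raw_call in (RawCall.ADENOMA, RawCall.CARCINOMA):
        call = ClipCall.ADENOMA
    else:  # hyperplastic or SSL
        call = ClipCall.NON_ADENOMA
    return call, reviewer_score(call, confidence)


def select_target_track(
    assignment_log: Sequence[tuple[int, int, int, str]],
    truth: dict[tuple[int, int], str],
    polyp_id: str,
) -> tuple[int | None, int]:
    """Pick the track representing the annotated target polyp of a clip.

    ``assignment_log`` rows are (frame_index, detection_index, track_id,
    stage); ``truth`` maps (frame_index, detection_index) -> polyp_id.
    Returns the track id holding the majority of the target's detections
    (ties broken toward the smaller id) and the number of distinct tracks
    the target was fragmented over (0 when the polyp was never detected).
    """
    votes: Counter[int] = Counter()
    for frame_index, det_index, track_id, _stage in assignment_log:
        if truth.get((frame_index, det_index)) == polyp_id:
            votes[track_id] += 1
    if not votes:
        return None, 0
    best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return best, len(votes)
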