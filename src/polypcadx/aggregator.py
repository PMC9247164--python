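"""Online temporal aggregation of per-frame characterization evidence.

For each tracked polyp the aggregator looks at a moving window over the most
recent frames of its history, keeps only frames whose imaging quality passes
the gate (q >= q_min), counts confident adenoma votes (score strictly above
0.5 + delta_high) and confident non-adenoma votes (score strictly below
0.5 - delta_low), and prints one of four live states:

* ``analysing``      — fewer than N_m valid frames seen in the window;
* ``adenoma``        — adenoma votes are a strict majority of valid frames;
* ``non_adenoma``    — non-adenoma votes are a strict majority;
* ``no_prediction``  — enough frames, but neither label holds a majority.

Majority is "strictly more than half of the valid frames", the only reading
under which the two labels are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .datamodel import FrameDecision, FrameState, TrackedPolyp

__all__ = ["AggregationParams", "count_votes", "decide_from_window", "decide_frame",
           "decide_sequence"]


@dataclass(frozen=True)
class AggregationParams:
    """Tunable parameters of the temporal aggregation rule.

    ``n_min`` — minimum number of valid frames before a decision is allowed
    (N_m); ``delta_low`` / ``delta_high`` — half-widths of the low-confidence
    band around 0.5; ``q_min`` — minimal imaging quality for a frame to count;
    ``window`` — number of most recent history frames considered.
    """

    n_min: int = 10
    delta_low: float = 0.1
    delta_high: float = 0.1
    q_min: int = 1
    window: int = 50

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if not (0.0 <= self.delta_low < 0.5 and 0.0 <= self.delta_high < 0.5):
            raise ValueError("delta_low and delta_high must lie in [0, 0.5)")
        if self.window < self.n_min:
            raise ValueError("window must be >= n_min")
        if self.q_min not in (0, 1, 2):
            raise ValueError("q_min must be 0, 1 or 2")


def count_votes(
    window: Sequence[tuple[float, int]], params: AggregationParams
) -> tuple[int, int, int]:
    """Count (N_a, N_na, N_valid) over a window of (score, quality) pairs.

    A frame is valid when its quality passes the gate; among valid frames a
    score strictly above ``0.5 + delta_high`` votes adenoma and a score
    strictly below ``0.5 - delta_low`` votes non-adenoma. Scores inside the
    closed band are low-confidence and vote for neither.
    """
    lo = 0.5 - params.delta_low
    hi = 0.5 + params.delta_high
    n_a = n_na = n_valid = 0
    for score, quality in window:
        if quality < params.q_min:
            continue
        n_valid += 1
        if score > hi:
            n_a += 1
        elif score < lo:
            n_na += 1
    return n_a, n_na, n_valid


def decide_from_window(
    window: Sequence[tuple[float, int]], params: AggregationParams
) -> tuple[FrameState, int, int, int]:
    """Apply the four-state rule to one window; returns (state, N_a, N_na,
    N_valid). Integer arithmetic (2*N > N_valid) keeps the majority test
    exact."""
    n_a, n_na, n_valid = count_votes(window, params)
    if n_valid < params.n_min:
        state = FrameState.ANALYSING
    elif 2 * n_a > n_valid:
        state = FrameState.ADENOMA
    elif 2 * n_na > n_valid:
        state = FrameState.NON_ADENOMA
    else:
        state = FrameState.NO_PREDICTION
    return state, n_a, n_na, n_valid


def decide_frame(
    track: TrackedPolyp, frame_index: int, params: AggregationParams
) -> FrameDecision:
    """Live decision for ``track`` at ``frame_index``, using the most recent
    ``params.window`` history entries up to and including that frame."""
    upto = [
        (s, q)
        for f, s, q in zip(track.frame_indices, track.scores, track.qualities)
        if f <= frame_index
    ]
    state, n_a, n_na, n_valid = decide_from_window(upto[-params.window :], params)
    return FrameDecision(
        track_id=track.track_id,
        frame_index=frame_index,
        state=state,
        n_adenoma=n_a,
        n_nonadenoma=n_na,
        n_valid=n_valid,
    )


def decide_sequence(
    scores: Sequence[float], qualities: Sequence[int], params: AggregationParams
) -> list[tuple[FrameState, int, int, int]]:
    """Decision at every position of a score/quality sequence, as if the
    frames arrived one by one. Position t uses the window of the most recent
    ``params.window`` entries ending at t."""
    pairs = list(zip(scores, qualities))
    return [
        decide_from_window(pairs[max(0, t + 1 - params.window) : t + 1], params)
        for t in range(len(pairs))
    ]
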