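"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by exhaustive enumeration
or naive recounting, independent of the library code paths they check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pytest

from polypcadx.aggregator import AggregationParams


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_assignment(cost: np.ndarray, gate: float) -> tuple[int, float]:
    """Exhaustive oracle for gated rectangular assignment: returns the
    (cardinality, total cost) of a maximum-cardinality matching over
    admissible pairs with minimal total cost."""
    m, n = cost.shape
    for k in range(min(m, n), 0, -1):
        best = np.inf
        for rows in combinations(range(m), k):
            for cols in permutations(range(n), k):
                tot = 0.0
                ok = True
                for r, c in zip(rows, cols):
                    if cost[r, c] > gate:
                        ok = False
                        break
                    tot += cost[r, c]
                if ok and tot < best:
                    best = tot
        if np.isfinite(best):
            return k, best
    return 0, 0.0


def naive_window_decision(
    scores, qualities, t: int, params: AggregationParams
) -> tuple[str, int, int, int]:
    """Recount-from-scratch oracle for the temporal aggregation rule."""
    window = list(zip(scores, qualities))[max(0, t + 1 - params.window) : t + 1]
    lo = 0.5 - params.delta_low
    hi = 0.5 + params.delta_high
    valid = [(s, q) for s, q in window if q >= params.q_min]
    n_a = sum(1 for s, _ in valid if s > hi)
    n_na = sum(1 for s, _ in valid if s < lo)
    n_valid = len(valid)
    if n_valid < params.n_min:
        state = "analysing"
    elif n_a > n_valid / 2:
        state = "adenoma"
    elif n_na > n_valid / 2:
        state = "non_adenoma"
    else:
        state = "no_prediction"
    return state, n_a, n_na, n_valid


def concordant_pair_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by direct enumeration of positive-negative pairs (ties 1/2)."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
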