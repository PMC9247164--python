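"""Per-detection characterization contract and geometric preprocessing.

A real device would run a trained characterization network plus an imaging
quality network on the cropped box content. This package fixes their output
contract — an adenoma probability in [0, 1], an appearance descriptor of
declared dimension, and a ternary quality grade — behind a pluggable scorer
interface, so the decision layer downstream is fully exercisable with stub
or synthetic scorers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .datamodel import BoundingBox, CharacterizationOutput

__all__ = ["CropWindow", "crop_with_margin", "Scorer", "ConstantScorer", "characterize"]

DEFAULT_MARGIN = 50     # pixels of context around the detection box
DEFAULT_OUT_SIZE = 512  # side of the square network input


@dataclass(frozen=True)
class CropWindow:
    """The frame region handed to the characterization network: the source
    box expanded by ``margin`` pixels on each side, clamped to the frame,
    to be rescaled to ``out_size`` x ``out_size``."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    out_size: int
    source: BoundingBox
    margin: float


def crop_with_margin(
    frame_width: int,
    frame_height: int,
    box: BoundingBox,
    margin: float = DEFAULT_MARGIN,
    out_size: int = DEFAULT_OUT_SIZE,
) -> CropWindow:
    """Expand ``box`` by ``margin`` pixels on all four sides and clamp to the
    frame bounds. Clamping (rather than padding) is used at borders so no
    pixel content is invented."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if box.x_max > frame_width or box.y_max > frame_height:
        raise ValueError("box lies outside the declared frame dimensions")
    x_min = max(0.0, box.x_min - margin)
    y_min = max(0.0, box.y_min - margin)
    x_max = min(float(frame_width), box.x_max + margin)
    y_max = min(float(frame_height), box.y_max + margin)
    if x_min >= x_max or y_min >= y_max:
        raise ValueError("crop window degenerate after clamping")
    return CropWindow(x_min, y_min, x_max, y_max, out_size, box, margin)


class Scorer(Protocol):
    """Plug-in contract for the characterization + quality models."""

    def __call__(
        self, window: CropWindow, content: np.ndarray | None = None
    ) -> tuple[float, np.ndarray, int]:
        """Return (adenoma score, appearance descriptor, ternary quality)."""
        ...


@dataclass(frozen=True)
class ConstantScorer:
    """Stub scorer: fixed score/quality, zero-mean fixed descriptor."""

    score: float = 0.5
    quality: int = 2
    descriptor_dim: int = 8

    def __call__(
        self, window: CropWindow, content: np.ndarray | None = None
    ) -> tuple[float, np.ndarray, int]:
        descriptor = np.zeros(self.descriptor_dim)
        descriptor[0] = 1.0
        return self.score, descriptor, self.quality


def characterize(
    window: CropWindow, scorer: Scorer, content: np.ndarray | None = None
) -> CharacterizationOutput:
    """Run a scorer on a crop window and normalize its output to the
    characterization contract. Scores are clipped into [0, 1] so downstream
    stages never see an out-of-range probability regardless of the scorer."""
    try:
        score, descriptor, quality = scorer(window, content)
    except Exception as exc:
        raise RuntimeError(
            f"scorer failed on window ({window.x_min}, {window.y_min}, "
            f"{window.x_max}, {window.y_max})"
        ) from exc
    score = float(min(1.0, max(0.0, score)))
    return CharacterizationOutput(
        score=score, descriptor=np.asarray(descriptor, dtype=float), quality=int(quality)
    )
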