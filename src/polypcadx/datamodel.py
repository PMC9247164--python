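"""Core domain types for the optical-characterization decision layer.

The types here mirror the objects a real-time colonoscopy CADx pipeline
passes between its stages: per-frame bounding-box detections with
characterization outputs, tracked polyps with per-frame histories, live
per-frame decisions, per-clip calls, and the ground-truth / reviewer-panel
records the evaluation statistics consume.

Coordinate convention: boxes are 0-based, in pixel units, and half-open,
``[x_min, x_max) x [y_min, y_max)``, so that areas and IoU are unambiguous
integer-friendly arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "LightMode",
    "Histology",
    "SizeClass",
    "FrameState",
    "ClipCall",
    "RawCall",
    "Confidence",
    "BoundingBox",
    "CharacterizationOutput",
    "Detection",
    "FrameRecord",
    "PolypRecord",
    "TrackedPolyp",
    "FrameDecision",
    "ClipDecision",
    "ReviewerResponse",
    "map_vienna",
]


class LightMode(str, Enum):
    """Illumination mode of a video frame: white light or blue light
    (narrow-band virtual chromoendoscopy)."""

    WL = "WL"
    BL = "BL"


class Histology(str, Enum):
    """Binary histology target: adenoma vs non-adenoma (hyperplastic and
    sessile serrated lesions fall in the non-adenoma class)."""

    ADENOMA = "adenoma"
    NON_ADENOMA = "non_adenoma"


class SizeClass(str, Enum):
    DIMINUTIVE = "diminutive"  # <= 5 mm
    SMALL = "small"            # 6-9 mm
    LARGE = "large"            # >= 10 mm


class FrameState(str, Enum):
    """Live four-state per-frame output of the temporal aggregator."""

    ANALYSING = "analysing"
    ADENOMA = "adenoma"
    NON_ADENOMA = "non_adenoma"
    NO_PREDICTION = "no_prediction"


class ClipCall(str, Enum):
    """Per-polyp three-state final call (per illumination mode)."""

    ADENOMA = "adenoma"
    NON_ADENOMA = "non_adenoma"
    UNDETERMINED = "undetermined"


class RawCall(str, Enum):
    """The five classes a reviewer may assign to a polyp videoclip."""

    ADENOMA = "adenoma"
    HYPERPLASTIC = "hyperplastic"
    SSL = "SSL"
    CARCINOMA = "carcinoma"
    UNCERTAIN = "uncertain"


class Confidence(str, Enum):
    """Four-level reviewer confidence, absent for 'uncertain' calls."""

    VERY_HIGH = "very_high"
    HIGH = "high"
    LOW = "low"
    VERY_LOW = "very_low"


def map_vienna(category: int) -> Histology:
    """Map a revised Vienna classification category (1-5) to the binary
    histology label.

    Categories 1 (negative for neoplasia) and 2 (indefinite for neoplasia)
    are non-adenoma; categories 3 (mucosal low-grade neoplasia), 4 (mucosal
    high-grade neoplasia) and 5 (submucosal invasion) are adenoma.
    """
    if category not in (1, 2, 3, 4, 5):
        raise ValueError(f"Vienna category must be in 1..5, got {category!r}")
    return Histology.NON_ADENOMA if category <= 2 else Histology.ADENOMA


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in frame pixel coordinates, half-open on both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if min(self.x_min, self.y_min) < 0:
            raise ValueError("box coordinates must be non-negative")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class CharacterizationOutput:
    """Per-detection output of the characterization stage.

    ``score`` is the probability that the box content is an adenoma,
    ``descriptor`` the appearance embedding used for re-identification,
    ``quality`` the ternary imaging-quality grade (0 = unusable, 2 = clear).
    """

    score: float
    descriptor: np.ndarray
    quality: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.quality not in (0, 1, 2):
            raise ValueError(f"quality must be 0, 1 or 2, got {self.quality}")
        d = np.asarray(self.descriptor, dtype=float)
        if d.ndim != 1:
            raise ValueError("descriptor must be a 1-D vector")
        if not np.all(np.isfinite(d)):
            raise ValueError("descriptor entries must be finite")
        object.__setattr__(self, "descriptor", d)


@dataclass
class Detection:
    """One localized polyp hypothesis in one frame."""

    frame_index: int
    box: BoundingBox
    char: CharacterizationOutput | None = None


@dataclass
class FrameRecord:
    """All detections of a single video frame plus frame metadata."""

    frame_index: int
    light_mode: LightMode
    frame_width: int
    frame_height: int
    detections: list[Detection] = field(default_factory=list)


@dataclass(frozen=True)
class PolypRecord:
    """Ground-truth record for one polyp of the cohort."""

    polyp_id: str
    vienna_category: int
    size_class: SizeClass

    @property
    def histology(self) -> Histology:
        return map_vienna(self.vienna_category)


@dataclass
class TrackedPolyp:
    """An actively followed polyp: identity plus per-frame history."""

    track_id: int
    frame_indices: list[int] = field(default_factory=list)
    boxes: list[BoundingBox] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    qualities: list[int] = field(default_factory=list)
    descriptors: list[np.ndarray] = field(default_factory=list)
    light_modes: list[LightMode] = field(default_factory=list)
    missed: int = 0
    active: bool = True

    @property
    def last_seen(self) -> int:
        return self.frame_indices[-1]

    @property
    def last_box(self) -> BoundingBox:
        return self.boxes[-1]

    @property
    def last_descriptor(self) -> np.ndarray:
        return self.descriptors[-1]

    def append(
        self,
        frame_index: int,
        box: BoundingBox,
        score: float,
        quality: int,
        descriptor: np.ndarray,
        light_mode: LightMode,
    ) -> None:
        if self.frame_indices and frame_index <= self.frame_indices[-1]:
            raise ValueError("track history frame indices must strictly increase")
        self.frame_indices.append(frame_index)
        self.boxes.append(box)
        self.scores.append(score)
        self.qualities.append(quality)
        self.descriptors.append(descriptor)
        self.light_modes.append(light_mode)
        self.missed = 0


@dataclass(frozen=True)
class FrameDecision:
    """Live aggregator output for one tracked polyp at one frame."""

    track_id: int
    frame_index: int
    state: FrameState
    n_adenoma: int
    n_nonadenoma: int
    n_valid: int


@dataclass(frozen=True)
class ClipDecision:
    """Per-polyp three-state call for one illumination mode."""

    polyp_id: str
    light_mode: LightMode
    call: ClipCall
    n_adenoma: int
    n_nonadenoma: int


@dataclass(frozen=True)
class ReviewerResponse:
    """One reviewer's survey answer for one polyp videoclip."""

    reviewer_id: str
    group: str  # "expert" | "non_expert"
    polyp_id: str
    raw_call: RawCall
    confidence: Confidence | None

    def __post_init__(self) -> None:
        if (self.confidence is None) != (self.raw_call is RawCall.UNCERTAIN):
            raise ValueError(
                "confidence must be present exactly when the call is not 'uncertain'"
            )
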