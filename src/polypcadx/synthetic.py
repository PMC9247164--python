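"""Synthetic study-data generators.

These generators stand in for everything a clinical reader study supplies:
detection streams with known polyp identities and histology-conditioned
score/quality processes (emulating the output of trained characterization
and quality networks on per-polyp videoclips), and reviewer panels with
group-specific accuracy, uncertainty, and confidence behaviour. Defaults
emulate the structure of a 513-polyp cohort (198 adenomas / 315
non-adenomas) reviewed by 10 expert and 11 non-expert endoscopists, with
clips carrying a white-light segment followed by a blue-light segment.

Everything is deterministic given a numpy Generator (or integer seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    BoundingBox,
    CharacterizationOutput,
    Confidence,
    Detection,
    FrameRecord,
    Histology,
    LightMode,
    PolypRecord,
    RawCall,
    ReviewerResponse,
    SizeClass,
)

__all__ = [
    "ScoreModel",
    "SceneConfig",
    "GroupBehavior",
    "PanelConfig",
    "generate_cohort",
    "generate_scene",
    "generate_panel",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class ScoreModel:
    """Histology-conditioned frame-score and quality process.

    The score process is hierarchical, mirroring how a frame classifier
    behaves on real lesions: each polyp first draws a latent difficulty -
    its own characteristic score level - from a Beta centred on the class
    mean (``polyp_concentration`` controls how much lesions of one class
    differ; some adenomas genuinely look hyperplastic), and every frame
    then draws a score from a Beta centred on the polyp level
    (``frame_concentration`` controls frame-to-frame jitter from viewpoint,
    zoom and illumination). Without the polyp level, temporal majority
    voting would wash out all frame noise and the clip-level accuracy would
    be trivially perfect. Qualities are i.i.d. draws from a three-point
    distribution over {0, 1, 2}.
    """

    adenoma_mean: float = 0.78
    non_adenoma_mean: float = 0.22
    polyp_concentration: float = 5.0
    frame_concentration: float = 8.0
    quality_probs: tuple[float, float, float] = (0.15, 0.35, 0.50)

    def __post_init__(self) -> None:
        for m in (self.adenoma_mean, self.non_adenoma_mean):
            if not 0.0 < m < 1.0:
                raise ValueError("score means must lie strictly inside (0, 1)")
        if self.polyp_concentration <= 0 or self.frame_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if abs(sum(self.quality_probs) - 1.0) > 1e-9 or min(self.quality_probs) < 0:
            raise ValueError("quality_probs must be a distribution over {0,1,2}")

    def class_mean(self, histology: Histology) -> float:
        return (
            self.adenoma_mean
            if histology is Histology.ADENOMA
            else self.non_adenoma_mean
        )

    def sample_polyp_mean(
        self, histology: Histology, rng: np.random.Generator
    ) -> float:
        mean = self.class_mean(histology)
        c = self.polyp_concentration
        return float(rng.beta(mean * c, (1.0 - mean) * c))

    def sample_frame_scores(
        self, polyp_mean: float, rng: np.random.Generator, size: int
    ) -> np.ndarray:
        m = min(max(polyp_mean, 1e-6), 1.0 - 1e-6)
        c = self.frame_concentration
        return rng.beta(m * c, (1.0 - m) * c, size=size)

    def draw_qualities(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(3, size=size, p=np.asarray(self.quality_probs))


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and noise model of one synthetic clip.

    Each polyp follows a clamped Gaussian random walk inside its own region
    of the frame (disjoint regions by default, so distinct polyps never
    overlap and ground-truth identity is unambiguous); detections are
    dropped with probability ``miss_prob`` per frame (occlusion), with an
    optional cap on consecutive misses. Appearance descriptors are drawn
    around mutually orthogonal per-polyp cluster centres.
    """

    n_frames_wl: int = 60
    n_frames_bl: int = 20
    frame_width: int = 1000
    frame_height: int = 1000
    step_sd: float = 8.0
    box_size_min: int = 80
    box_size_max: int = 160
    miss_prob: float = 0.10
    max_consecutive_miss: int | None = None
    descriptor_dim: int = 16
    descriptor_noise: float = 0.05
    disjoint_regions: bool = True
    #: fraction of clips whose blue-light segment is cut short (the
    #: endoscopist moved on before a full virtual-chromoendoscopy pass),
    #: typically leaving too few frames for a blue-light decision
    bl_dropout: float = 0.25

    def __post_init__(self) -> None:
        if self.n_frames_wl + self.n_frames_bl < 1:
            raise ValueError("a clip needs at least one frame")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if not 0.0 <= self.bl_dropout <= 1.0:
            raise ValueError("bl_dropout must lie in [0, 1]")
        if self.box_size_min > self.box_size_max or self.box_size_min <= 0:
            raise ValueError("invalid box size range")

    @property
    def n_frames(self) -> int:
        return self.n_frames_wl + self.n_frames_bl


def generate_cohort(
    n_polyps: int = 513,
    adenoma_prevalence: float = 198 / 513,
    seed: int | np.random.Generator = 0,
    size_probs: tuple[float, float, float] = (0.60, 0.25, 0.15),
    adenoma_vienna_probs: tuple[float, float, float] = (0.85, 0.12, 0.03),
    non_adenoma_vienna_probs: tuple[float, float] = (0.90, 0.10),
) -> list[PolypRecord]:
    """Draw a polyp cohort: Bernoulli histology labels at the given
    prevalence, Vienna categories consistent with the label (1-2 for
    non-adenoma, 3-5 for adenoma), and size classes (diminutive / small /
    large)."""
    if not 0.0 <= adenoma_prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = _as_rng(seed)
    records = []
    width = len(str(max(n_polyps - 1, 1)))
    for i in range(n_polyps):
        is_adenoma = rng.random() < adenoma_prevalence
        if is_adenoma:
            vienna = int(rng.choice([3, 4, 5], p=np.asarray(adenoma_vienna_probs)))
        else:
            vienna = int(rng.choice([1, 2], p=np.asarray(non_adenoma_vienna_probs)))
        size = SizeClass(
            rng.choice(
                [s.value for s in SizeClass], p=np.asarray(size_probs)
            )
        )
        records.append(
            PolypRecord(
                polyp_id=f"P{i:0{width}d}", vienna_category=vienna, size_class=size
            )
        )
    return records


def _regions(
    n: int, width: int, height: int
) -> list[tuple[float, float, float, float]]:
    """Partition the frame into an n-cell grid of disjoint regions."""
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    cw, ch = width / cols, height / rows
    out = []
    for i in range(n):
        r, c = divmod(i, cols)
        out.append((c * cw, r * ch, (c + 1) * cw, (r + 1) * ch))
    return out


def _orthonormal_centres(
    n: int, dim: int, rng: np.random.Generator
) -> np.ndarray:
    if dim < n:
        raise ValueError(
            f"descriptor_dim={dim} cannot host {n} orthogonal cluster centres"
        )
    q, _ = np.linalg.qr(rng.standard_normal((dim, n)))
    return q.T  # (n, dim)


def generate_scene(
    scene: SceneConfig,
    polyps: list[PolypRecord],
    score_model: ScoreModel,
    seed: int | np.random.Generator = 0,
) -> tuple[list[FrameRecord], list[dict]]:
    """Simulate one clip containing the given polyps.

    Returns the frame records (WL segment then BL segment) and the
    ground-truth identity table: one ``{"frame_index", "detection_index",
    "polyp_id"}`` row per emitted detection. A ``bl_dropout`` fraction of
    clips carries a truncated blue-light segment.
    """
    rng = _as_rng(seed)
    n_p = len(polyps)
    if n_p == 0:
        raise ValueError("a scene needs at least one polyp")
    if scene.disjoint_regions:
        regions = _regions(n_p, scene.frame_width, scene.frame_height)
    else:
        regions = [(0.0, 0.0, float(scene.frame_width), float(scene.frame_height))] * n_p

    sizes = []
    centres = []
    for rx0, ry0, rx1, ry1 in regions:
        max_w = min(scene.box_size_max, (rx1 - rx0) * 0.9)
        max_h = min(scene.box_size_max, (ry1 - ry0) * 0.9)
        if max_w < scene.box_size_min or max_h < scene.box_size_min:
            raise ValueError("box size range infeasible for the region geometry")
        w = rng.uniform(scene.box_size_min, max_w)
        h = rng.uniform(scene.box_size_min, max_h)
        cx = rng.uniform(rx0 + w / 2, rx1 - w / 2)
        cy = rng.uniform(ry0 + h / 2, ry1 - h / 2)
        sizes.append((w, h))
        centres.append([cx, cy])
    cluster = _orthonormal_centres(n_p, scene.descriptor_dim, rng)

    scores = np.stack(
        [
            score_model.sample_frame_scores(
                score_model.sample_polyp_mean(p.histology, rng), rng, scene.n_frames
            )
            for p in polyps
        ]
    )
    qualities = np.stack(
        [score_model.draw_qualities(rng, scene.n_frames) for p in polyps]
    )

    # a truncated blue-light pass leaves the clip short of BL frames
    n_bl = scene.n_frames_bl
    if n_bl > 0 and rng.random() < scene.bl_dropout:
        n_bl = int(rng.integers(0, max(1, scene.n_frames_bl // 2)))
    n_frames = scene.n_frames_wl + n_bl

    frames: list[FrameRecord] = []
    truth: list[dict] = []
    consecutive_miss = [0] * n_p
    for t in range(n_frames):
        mode = LightMode.WL if t < scene.n_frames_wl else LightMode.BL
        detections: list[Detection] = []
        for j in range(n_p):
            rx0, ry0, rx1, ry1 = regions[j]
            w, h = sizes[j]
            step = rng.normal(0.0, scene.step_sd, 2)
            centres[j][0] = float(np.clip(centres[j][0] + step[0], rx0 + w / 2, rx1 - w / 2))
            centres[j][1] = float(np.clip(centres[j][1] + step[1], ry0 + h / 2, ry1 - h / 2))
            missed = rng.random() < scene.miss_prob
            if (
                scene.max_consecutive_miss is not None
                and consecutive_miss[j] >= scene.max_consecutive_miss
            ):
                missed = False
            if missed:
                consecutive_miss[j] += 1
                continue
            consecutive_miss[j] = 0
            box = BoundingBox(
                x_min=centres[j][0] - w / 2,
                y_min=centres[j][1] - h / 2,
                x_max=centres[j][0] + w / 2,
                y_max=centres[j][1] + h / 2,
            )
            descriptor = cluster[j] + scene.descriptor_noise * rng.standard_normal(
                scene.descriptor_dim
            )
            char = CharacterizationOutput(
                score=float(scores[j, t]),
                descriptor=descriptor,
                quality=int(qualities[j, t]),
            )
            truth.append(
                {
                    "frame_index": t,
                    "detection_index": len(detections),
                    "polyp_id": polyps[j].polyp_id,
                }
            )
            detections.append(Detection(frame_index=t, box=box, char=char))
        frames.append(
            FrameRecord(
                frame_index=t,
                light_mode=mode,
                frame_width=scene.frame_width,
                frame_height=scene.frame_height,
                detections=detections,
            )
        )
    return frames, truth


# ---------------------------------------------------------------------------
# Reviewer panels


@dataclass(frozen=True)
class GroupBehavior:
    """Per-group response process: probability of a correct call given the
    polyp's histology, and probability of abstaining ('uncertain')."""

    acc_adenoma: float
    acc_non_adenoma: float
    undetermined_prob: float

    def __post_init__(self) -> None:
        for p in (self.acc_adenoma, self.acc_non_adenoma, self.undetermined_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PanelConfig:
    """Reviewer-panel generator configuration.

    Group accuracies default near the performance a multi-reader study of
    this design reports (experts more accurate than non-experts on both
    classes, both with rare abstentions). ``reader_sd`` is the SD of a
    per-reader multiplicative effect on the log-accuracy scale — the random
    intercept the accuracy model estimates. Correct adenoma calls split
    between 'adenoma' and 'carcinoma'; correct non-adenoma calls between
    'hyperplastic' and 'SSL'; confidence is drawn conditional on
    correctness, skewing high when the call is correct.
    """

    n_experts: int = 10
    n_nonexperts: int = 11
    expert: GroupBehavior = field(
        default_factory=lambda: GroupBehavior(0.77, 0.86, 0.014)
    )
    non_expert: GroupBehavior = field(
        default_factory=lambda: GroupBehavior(0.72, 0.81, 0.019)
    )
    reader_sd: float = 0.08
    carcinoma_frac: float = 0.05
    ssl_frac: float = 0.30
    conf_correct: tuple[float, float, float, float] = (0.40, 0.35, 0.18, 0.07)
    conf_incorrect: tuple[float, float, float, float] = (0.10, 0.25, 0.40, 0.25)

    def __post_init__(self) -> None:
        if self.n_experts < 1 or self.n_nonexperts < 1:
            raise ValueError("each group needs at least one reviewer")
        for dist in (self.conf_correct, self.conf_incorrect):
            if abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                raise ValueError("confidence distributions must be proper")


_CONF_LEVELS = (
    Confidence.VERY_HIGH,
    Confidence.HIGH,
    Confidence.LOW,
    Confidence.VERY_LOW,
)

_CAP_TAU = 0.025


def _capped_accuracy(base: float, effect: float) -> float:
    """Reader-level accuracy: log-scale random effect with a smooth cap
    below 1, ``p = exp(-tau softplus(-(log base + effect)/tau))``.

    This is the generative counterpart of the log-link mixed accuracy
    model: a hard ``min(1, base * e^effect)`` would put an atom of perfect
    readers at p = 1, a heavy-tailed cluster outlier no random-intercept
    model describes."""
    x = math.log(base) + effect
    return float(math.exp(-_CAP_TAU * np.logaddexp(0.0, -x / _CAP_TAU)))


def generate_panel(
    panel: PanelConfig,
    cohort: list[PolypRecord],
    seed: int | np.random.Generator = 0,
) -> list[ReviewerResponse]:
    """Simulate the full reviewer-response table for a cohort."""
    rng = _as_rng(seed)
    responses: list[ReviewerResponse] = []
    groups = [("expert", panel.expert, panel.n_experts, "exp"), (
        "non_expert", panel.non_expert, panel.n_nonexperts, "nov")]
    for group_name, behave, n_rev, prefix in groups:
        for r in range(n_rev):
            effect = rng.normal(0.0, panel.reader_sd)
            if panel.reader_sd > 0 and 0.0 < behave.acc_adenoma:
                acc_a = _capped_accuracy(behave.acc_adenoma, effect)
            else:
                acc_a = behave.acc_adenoma
            if panel.reader_sd > 0 and 0.0 < behave.acc_non_adenoma:
                acc_na = _capped_accuracy(behave.acc_non_adenoma, effect)
            else:
                acc_na = behave.acc_non_adenoma
            rid = f"{prefix}{r:02d}"
            for polyp in cohort:
                if rng.random() < behave.undetermined_prob:
                    responses.append(
                        ReviewerResponse(rid, group_name, polyp.polyp_id,
                                         RawCall.UNCERTAIN, None)
                    )
                    continue
                is_adenoma = polyp.histology is Histology.ADENOMA
                acc = acc_a if is_adenoma else acc_na
                correct = rng.random() < acc
                call_adenoma = correct == is_adenoma
                if call_adenoma:
                    raw = (
                        RawCall.CARCINOMA
                        if rng.random() < panel.carcinoma_frac
                        else RawCall.ADENOMA
                    )
                else:
                    raw = (
                        RawCall.SSL
                        if rng.random() < panel.ssl_frac
                        else RawCall.HYPERPLASTIC
                    )
                dist = panel.conf_correct if correct else panel.conf_incorrect
                conf = _CONF_LEVELS[int(rng.choice(4, p=np.asarray(dist)))]
                responses.append(
                    ReviewerResponse(rid, group_name, polyp.polyp_id, raw, conf)
                )
    return responses
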