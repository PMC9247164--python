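"""Declarative study configuration (single YAML file).

All randomness in the package flows from the single ``seed`` here; child
generators for the cohort, the per-clip scenes, and the reviewer panel are
spawned from it deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aggregator import AggregationParams
from .synthetic import GroupBehavior, PanelConfig, SceneConfig, ScoreModel
from .tracker import TrackerParams

__all__ = ["CohortConfig", "StudyConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class CohortConfig:
    n_polyps: int = 513
    adenoma_prevalence: float = 198 / 513


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 0
    n_boot: int = 10_000
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    panel: PanelConfig = field(default_factory=PanelConfig)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    aggregator: AggregationParams = field(default_factory=AggregationParams)


def _build(cls, data):
    """Construct a (possibly nested) dataclass from a plain dict, leaving
    untouched values that are already of the right type."""
    if data is None:
        return cls()
    if isinstance(data, cls):
        return data
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise KeyError(f"unknown {cls.__name__} field: {key!r}")
        ftype = fields[key].type
        if isinstance(value, dict) and ftype in _NESTED:
            value = _build(_NESTED[ftype], value)
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "CohortConfig": CohortConfig,
    "SceneConfig": SceneConfig,
    "ScoreModel": ScoreModel,
    "PanelConfig": PanelConfig,
    "TrackerParams": TrackerParams,
    "AggregationParams": AggregationParams,
    "GroupBehavior": GroupBehavior,
}


def load_config(path: str | Path | None = None, **overrides) -> StudyConfig:
    """Load a study configuration from YAML (all sections optional), then
    apply keyword overrides (e.g. ``seed=...``)."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = StudyConfig(
        seed=int(data.get("seed", 0)),
        n_boot=int(data.get("n_boot", 10_000)),
        cohort=_build(CohortConfig, data.get("cohort")),
        scene=_build(SceneConfig, data.get("scene")),
        score_model=_build(ScoreModel, data.get("score_model")),
        panel=_build(PanelConfig, data.get("panel")),
        tracker=_build(TrackerParams, data.get("tracker")),
        aggregator=_build(AggregationParams, data.get("aggregator")),
    )
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
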