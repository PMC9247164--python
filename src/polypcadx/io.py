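"""Readers and writers for detection streams and study tables.

Detection streams are JSON Lines: a header record carrying frame dimensions
and descriptor dimensionality, followed by one record per frame. Tables
(polyp cohort, reviewer panel, output logs) are CSV with headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    BoundingBox,
    CharacterizationOutput,
    Confidence,
    Detection,
    FrameRecord,
    LightMode,
    PolypRecord,
    RawCall,
    ReviewerResponse,
    SizeClass,
)

__all__ = [
    "StreamFormatError",
    "StreamHeader",
    "read_detection_stream",
    "write_detection_stream",
    "read_cohort",
    "write_cohort",
    "read_panel",
    "write_panel",
    "read_manifest",
    "write_manifest",
]


class StreamFormatError(ValueError):
    """Raised when a detection-stream file violates the format contract."""


@dataclass(frozen=True)
class StreamHeader:
    clip_id: str
    frame_width: int
    frame_height: int
    descriptor_dim: int


def write_detection_stream(
    path: str | Path, header: StreamHeader, frames: Iterable[FrameRecord]
) -> None:
    """Write a detection stream as JSON Lines (header record first)."""
    with open(path, "w") as fh:
        fh.write(
            json.dumps(
                {
                    "type": "header",
                    "clip_id": header.clip_id,
                    "frame_width": header.frame_width,
                    "frame_height": header.frame_height,
                    "descriptor_dim": header.descriptor_dim,
                }
            )
            + "\n"
        )
        for frame in frames:
            rec = {
                "type": "frame",
                "frame_index": frame.frame_index,
                "light_mode": frame.light_mode.value,
                "detections": [
                    {
                        "box": list(det.box.as_tuple()),
                        "score": det.char.score,
                        "quality": det.char.quality,
                        "descriptor": det.char.descriptor.tolist(),
                    }
                    for det in frame.detections
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_detection_stream(
    path: str | Path,
) -> tuple[StreamHeader | None, list[FrameRecord]]:
    """Read a JSON Lines detection stream.

    Returns the header (``None`` for an empty file) and the frame records in
    frame order. Raises :class:`StreamFormatError` naming the offending line
    on malformed input, non-monotone frame indices, invalid boxes, or
    descriptor-dimensionality mismatches.
    """
    header: StreamHeader | None = None
    frames: list[FrameRecord] = []
    last_index: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            kind = obj.get("type")
            if kind == "header":
                if header is not None:
                    raise StreamFormatError(f"line {lineno}: duplicate header")
                header = StreamHeader(
                    clip_id=str(obj["clip_id"]),
                    frame_width=int(obj["frame_width"]),
                    frame_height=int(obj["frame_height"]),
                    descriptor_dim=int(obj["descriptor_dim"]),
                )
                continue
            if kind != "frame":
                raise StreamFormatError(f"line {lineno}: unknown record type {kind!r}")
            if header is None:
                raise StreamFormatError(f"line {lineno}: frame record before header")
            idx = int(obj["frame_index"])
            if last_index is not None and idx <= last_index:
                raise StreamFormatError(
                    f"line {lineno}: frame_index {idx} not greater than {last_index}"
                )
            last_index = idx
            detections = []
            for d_i, d in enumerate(obj.get("detections", [])):
                try:
                    box = BoundingBox(*d["box"])
                except ValueError as exc:
                    raise StreamFormatError(
                        f"line {lineno}: detection {d_i}: {exc}"
                    ) from exc
                descriptor = np.asarray(d["descriptor"], dtype=float)
                if descriptor.shape != (header.descriptor_dim,):
                    raise StreamFormatError(
                        f"line {lineno}: detection {d_i}: descriptor has "
                        f"dimension {descriptor.size}, header declares "
                        f"{header.descriptor_dim}"
                    )
                char = CharacterizationOutput(
                    score=float(d["score"]),
                    descriptor=descriptor,
                    quality=int(d["quality"]),
                )
                detections.append(Detection(frame_index=idx, box=box, char=char))
            frames.append(
                FrameRecord(
                    frame_index=idx,
                    light_mode=LightMode(obj["light_mode"]),
                    frame_width=header.frame_width,
                    frame_height=header.frame_height,
                    detections=detections,
                )
            )
    return header, frames


# ---------------------------------------------------------------------------
# CSV tables


def write_cohort(path: str | Path, cohort: Iterable[PolypRecord]) -> None:
    df = pd.DataFrame(
        {
            "polyp_id": [p.polyp_id for p in cohort],
            "vienna_category": [p.vienna_category for p in cohort],
            "size_class": [p.size_class.value for p in cohort],
        }
    )
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PolypRecord]:
    df = pd.read_csv(path, dtype={"polyp_id": str})
    return [
        PolypRecord(
            polyp_id=row.polyp_id,
            vienna_category=int(row.vienna_category),
            size_class=SizeClass(row.size_class),
        )
        for row in df.itertuples()
    ]


def write_panel(path: str | Path, responses: Iterable[ReviewerResponse]) -> None:
    df = pd.DataFrame(
        {
            "reviewer_id": [r.reviewer_id for r in responses],
            "group": [r.group for r in responses],
            "polyp_id": [r.polyp_id for r in responses],
            "call": [r.raw_call.value for r in responses],
            "confidence": [
                "" if r.confidence is None else r.confidence.value for r in responses
            ],
        }
    )
    df.to_csv(path, index=False)


def read_panel(path: str | Path) -> list[ReviewerResponse]:
    df = pd.read_csv(
        path, dtype={"reviewer_id": str, "polyp_id": str}, keep_default_na=False
    )
    out = []
    for row in df.itertuples():
        conf = None if row.confidence == "" else Confidence(row.confidence)
        out.append(
            ReviewerResponse(
                reviewer_id=row.reviewer_id,
                group=row.group,
                polyp_id=row.polyp_id,
                raw_call=RawCall(row.call),
                confidence=conf,
            )
        )
    return out


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    """Manifest table: clip_id, polyp_id, path, first_frame, last_frame."""
    cols = ["clip_id", "polyp_id", "path", "first_frame", "last_frame"]
    manifest[cols].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"clip_id": str, "polyp_id": str, "path": str})
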