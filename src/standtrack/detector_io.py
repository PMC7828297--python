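"""Detection file I/O in an MOT-style text dialect, plus grid-geometry
helpers for single-shot detectors.

The file format is comma-separated lines

    frame,id,x,y,w,h,conf[,...]

with 0-based frame indices and top-left + width/height box coordinates.
The id field is ignored on read (written as -1 for raw detections); extra
trailing fields are ignored. Corner-format :class:`~standtrack.geometry.Box`
objects are produced at this boundary, fixing the corner-vs-center
convention in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from .geometry import Box

__all__ = [
    "DetectionRecord",
    "GridSpec",
    "read_detections",
    "write_detections",
    "kernel_depth",
    "grid_sizes",
]


@dataclass(frozen=True)
class DetectionRecord:
    """One detection line: frame index, top-left box, confidence."""

    frame: int
    x: float
    y: float
    w: float
    h: float
    confidence: float = 1.0
    object_id: int = -1

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame index must be nonnegative, got {self.frame}")
        if not (self.w > 0 and self.h > 0):
            raise ValueError(
                f"box width and height must be positive, got w={self.w}, h={self.h}"
            )

    def to_box(self) -> Box:
        return Box.from_xywh(self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a gridded single-shot detector head.

    ``boxes_per_cell`` boxes are predicted per grid cell, each carrying four
    box attributes plus one confidence score plus ``num_classes`` class
    scores; prediction grids are the input downsampled by each stride.
    """

    input_size: int
    strides: Tuple[int, ...]
    boxes_per_cell: int = 3
    num_classes: int = 1

    def __post_init__(self) -> None:
        if self.boxes_per_cell < 1:
            raise ValueError("boxes_per_cell must be >= 1")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size < 1:
            raise ValueError("input_size must be positive")
        if not self.strides:
            raise ValueError("at least one stride is required")
        for stride in self.strides:
            if stride < 1 or self.input_size % stride != 0:
                raise ValueError(
                    f"input size {self.input_size} is not divisible by stride {stride}"
                )


def kernel_depth(spec: GridSpec) -> int:
    """Channel depth of the 1x1 detection kernel: B * (5 + C)."""
    return spec.boxes_per_cell * (5 + spec.num_classes)


def grid_sizes(spec: GridSpec) -> Tuple[int, ...]:
    """Side length of each prediction grid, input_size / stride per stride."""
    return tuple(spec.input_size // s for s in spec.strides)


def parse_detection_line(line: str) -> DetectionRecord:
    fields = [f.strip() for f in line.split(",")]
    if len(fields) < 6:
        raise ValueError(f"expected at least 6 comma-separated fields, got {len(fields)}")
    frame = int(fields[0])
    object_id = int(float(fields[1]))
    x, y, w, h = (float(f) for f in fields[2:6])
    conf = float(fields[6]) if len(fields) > 6 and fields[6] != "" else 1.0
    return DetectionRecord(
        frame=frame, x=x, y=y, w=w, h=h, confidence=conf, object_id=object_id
    )


def read_detections(
    path: Union[str, Path],
    conf_threshold: float = 0.0,
) -> List[Tuple[int, List[Tuple[Box, float]]]]:
    """Read a detection file into per-frame box lists.

    Returns ``[(frame, [(box, confidence), ...]), ...]`` sorted by frame,
    keeping only detections with confidence >= ``conf_threshold``. An empty
    file yields an empty stream.

    Raises
    ------
    ValueError
        On an unparseable line, naming its 1-based line number.
    """
    frames: Dict[int, List[Tuple[Box, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rec = parse_detection_line(line)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if rec.confidence < conf_threshold:
                continue
            frames.setdefault(rec.frame, []).append((rec.to_box(), rec.confidence))
    return [(frame, frames[frame]) for frame in sorted(frames)]


def read_detection_records(path: Union[str, Path]) -> List[DetectionRecord]:
    """Read a detection file as raw records, keeping object ids."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                records.append(parse_detection_line(line))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_detections(
    path: Union[str, Path], records: Iterable[DetectionRecord]
) -> None:
    """Write records in the same dialect read by :func:`read_detections`."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.frame},{rec.object_id},{rec.x:.4f},{rec.y:.4f},"
                f"{rec.w:.4f},{rec.h:.4f},{rec.confidence:.6f}\n"
            )


def boxes_only(
    stream: Sequence[Tuple[int, List[Tuple[Box, float]]]]
) -> List[Tuple[int, List[Box]]]:
    """Strip confidences from a read stream for the tracking pipeline."""
    return [(frame, [box for box, _ in dets]) for frame, dets in stream]
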