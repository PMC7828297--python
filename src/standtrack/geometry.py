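"""Axis-aligned boxes, the box <-> (center, area, aspect) mapping, IoU, and
2-D segment intersection.

Coordinates are continuous pixels: origin at the top-left of the image,
x increasing rightward, y increasing downward. Boxes are real rectangles
(sub-pixel corners allowed), stored corner-format ``(x1, y1, x2, y2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

__all__ = [
    "Box",
    "Measurement",
    "Segment",
    "iou",
    "box_to_measurement",
    "measurement_to_box",
    "segments_intersect",
]

Point = Tuple[float, float]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with strictly positive width and height."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for c in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(c):
                raise ValueError(f"box coordinates must be finite, got {self!r}")
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"box must have positive width and height, got {self!r}"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Point:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        """Build from top-left corner plus width/height."""
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> Tuple[float, float, float, float]:
        return (self.x1, self.y1, self.width, self.height)


@dataclass(frozen=True)
class Measurement:
    """Observation-space view of a box: center (u, v), area s, aspect r = w/h."""

    u: float
    v: float
    s: float
    r: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.r > 0):
            raise ValueError(f"area and aspect ratio must be positive, got {self!r}")


@dataclass(frozen=True)
class Segment:
    """Directed 2-D segment between two distinct points."""

    p1: Point
    p2: Point

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("segment endpoints must be distinct")


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes, in [0, 1].

    Boxes that merely share an edge have zero intersection area and IoU 0.
    """
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def box_to_measurement(b: Box) -> Measurement:
    """Map a box to (center u, center v, area s, aspect ratio r)."""
    u, v = b.center
    return Measurement(u=u, v=v, s=b.area, r=b.width / b.height)


def measurement_to_box(m: Measurement) -> Box:
    """Inverse of :func:`box_to_measurement`: w = sqrt(s*r), h = sqrt(s/r)."""
    w = math.sqrt(m.s * m.r)
    h = math.sqrt(m.s / m.r)
    return Box(m.u - w / 2.0, m.v - h / 2.0, m.u + w / 2.0, m.v + h / 2.0)


def _orient(p: Point, q: Point, r: Point) -> int:
    """Sign of the cross product (q-p) x (r-p): +1 CCW, -1 CW, 0 collinear."""
    val = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
    if val > 0:
        return 1
    if val < 0:
        return -1
    return 0


def _on_segment(p: Point, q: Point, r: Point) -> bool:
    """Whether collinear point r lies on the closed segment pq."""
    return (
        min(p[0], q[0]) <= r[0] <= max(p[0], q[0])
        and min(p[1], q[1]) <= r[1] <= max(p[1], q[1])
    )


def segments_intersect(a: Segment, b: Segment) -> bool:
    """True iff the closed segments share at least one point.

    Endpoint contact and collinear overlap both count as intersection, so a
    trajectory that only just reaches the line is still a crossing.
    """
    p1, q1, p2, q2 = a.p1, a.p2, b.p1, b.p2
    o1 = _orient(p1, q1, p2)
    o2 = _orient(p1, q1, q2)
    o3 = _orient(p2, q2, p1)
    o4 = _orient(p2, q2, q1)

    if o1 != o2 and o3 != o4:
        return True
    if o1 == 0 and _on_segment(p1, q1, p2):
        return True
    if o2 == 0 and _on_segment(p1, q1, q2):
        return True
    if o3 == 0 and _on_segment(p2, q2, p1):
        return True
    if o4 == 0 and _on_segment(p2, q2, q1):
        return True
    return False
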