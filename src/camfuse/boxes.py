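"""Axis-aligned bounding boxes: overlap (IOU) and non-maximum suppression.

Boxes are continuous pixel regions in corner form (x_min, y_min, x_max,
y_max); a center/size form is accepted on input by :func:`BoundingBox.from_center`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["BoundingBox", "Detection", "iou", "nms", "vertical_center"]


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"invalid box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def from_center(cls, cx: float, cy: float, width: float, height: float) -> "BoundingBox":
        return cls(cx - width / 2.0, cy - height / 2.0, cx + width / 2.0, cy + height / 2.0)

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)


@dataclass(frozen=True)
class Detection:
    """A detector output: a box with a class label and an accuracy fraction."""

    box: BoundingBox
    label: str = ""
    score: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"detection score must lie in [0, 1], got {self.score}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1].

    Symmetric; 0 for disjoint or edge-touching boxes; defined as 0 when the
    union has zero area (two degenerate boxes) so no division by zero occurs.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def nms(detections: Sequence[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy score-descending non-maximum suppression.

    The highest-scoring box of each overlap group is kept; any remaining box
    whose IOU with a kept box exceeds ``iou_threshold`` is discarded.  Ties
    on score break toward smaller x_min then y_min so the result is
    deterministic.  Output is in descending score order.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must lie in [0, 1], got {iou_threshold}")
    order = sorted(detections, key=lambda d: (-d.score, d.box.x_min, d.box.y_min))
    kept: list[Detection] = []
    for cand in order:
        if all(iou(cand.box, k.box) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def vertical_center(b: BoundingBox) -> float:
    """Vertical center of the box in pixels from the top of the view."""
    return (b.y_min + b.y_max) / 2.0
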