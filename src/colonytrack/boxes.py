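"""Axis-aligned bounding boxes and overlap arithmetic.

Boxes are pixel-space, 0-based, top-left origin, half-open:
a box covers ``[x_min, x_min + width) x [y_min, y_min + height)``.
Conversions to 1-based external dialects happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoundingBox", "iou", "iou_matrix"]


@dataclass(frozen=True)
class BoundingBox:
    """Rectangle with strictly positive extent.

    Coordinates are floats; premature integer rounding is avoided so that
    sub-pixel drift survives round trips.
    """

    x_min: float
    y_min: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"box extent must be positive, got {self.width} x {self.height}"
            )

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min + self.width / 2.0, self.y_min + self.height / 2.0)

    def clip(self, image_width: float, image_height: float) -> "BoundingBox":
        """Clip to image bounds; raises if nothing remains."""
        x0 = max(self.x_min, 0.0)
        y0 = max(self.y_min, 0.0)
        x1 = min(self.x_max, float(image_width))
        y1 = min(self.y_max, float(image_height))
        if x1 <= x0 or y1 <= y0:
            raise ValueError("box lies entirely outside the image")
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]. Symmetric."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou_matrix(rows: list[BoundingBox], cols: list[BoundingBox]) -> np.ndarray:
    """Pairwise IoU, shape (len(rows), len(cols))."""
    out = np.zeros((len(rows), len(cols)), dtype=float)
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            out[i, j] = iou(a, b)
    return out
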