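"""Per-slice object detection: localize dark blobs on a brightfield slice
and classify them as candidate / cell / cluster / colony.

The reference detector is classical — background flattening, thresholding
(Otsu by default), connected components, a Laplacian focus measure, and a
size-based classifier on cell-equivalents — so the pipeline runs without
trained network weights. Any callable mapping an image to a list of
:class:`Detection` satisfies the same contract and can substitute it
(e.g. an adapter reading precomputed neural-network detections);
downstream tracking depends only on that contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .boxes import BoundingBox, iou
from .classes import CANDIDATE, CELL, CLUSTER, COLONY, COLONY_MIN_CELLS

__all__ = [
    "BoundingBox",
    "Detection",
    "DetectorConfig",
    "segment_slice",
    "focus_score",
    "classify_blob",
    "nms",
    "detect_slice",
    "detect_stack",
]


@dataclass(frozen=True)
class Detection:
    """One classified box on one slice, confidence in [0, 1]."""

    bbox: BoundingBox
    label: str
    confidence: float
    slice_index: int = -1

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")
        if self.label not in (CANDIDATE, CELL, CLUSTER, COLONY):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class DetectorConfig:
    """Reference-detector hyperparameters.

    ``cell_area`` is the pixel area of one cell-equivalent; blob class is
    assigned from round(area / cell_area). ``intensity_threshold`` of None
    selects Otsu thresholding on the flattened image. ``focus_threshold``
    separates in-focus objects (classified by size) from out-of-focus
    candidates. Defaults are exposed, not claimed optimal; the tuning
    harness in :mod:`colonytrack.moteval` searches them jointly with the
    tracker's.
    """

    intensity_threshold: float | None = None  # None -> Otsu
    min_area: float = 9.0  # px^2
    cell_area: float = 28.0  # px^2 of one cell-equivalent
    focus_threshold: float = 0.002
    confidence_threshold: float = 0.1
    nms_iou: float = 0.6
    background_filter_size: int = 0  # 0 -> global median background

    def validate(self) -> None:
        if self.min_area > self.cell_area:
            raise ValueError("min_area must be <= cell_area")
        for name in ("confidence_threshold", "nms_iou"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.focus_threshold < 0:
            raise ValueError("focus_threshold must be >= 0")


def _flatten_background(image: np.ndarray, size: int) -> np.ndarray:
    """Object signal = background minus image (objects are dark).

    With ``size`` = 0 the background is the global median (appropriate
    for flat-field images); a positive size uses a local median window so
    slowly varying illumination does not shift the threshold.
    """
    if size > 1 and min(image.shape) > size:
        background = ndimage.median_filter(image, size=size)
    else:
        background = np.full_like(image, float(np.median(image)))
    return np.clip(background - image, 0.0, None)


def _segment_regions(
    image: np.ndarray, config: DetectorConfig
) -> list[tuple[BoundingBox, float]]:
    """Connected components of the thresholded signal as (box, area).

    The reported area is the *half-peak* pixel count of each component —
    pixels whose signal exceeds half the component's peak. For a disk
    blurred by a Gaussian narrower than its radius, the half-peak contour
    sits at the true rim, so the area estimate is nearly independent of
    both the global threshold level and moderate defocus.
    """
    config.validate()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D grayscale image")
    signal = _flatten_background(image, config.background_filter_size)
    if config.intensity_threshold is not None:
        thr = config.intensity_threshold
    else:
        # Otsu needs contrast; a flat field has no objects.
        if float(signal.max() - signal.min()) < 1e-6:
            return []
        thr = float(filters.threshold_otsu(signal))
        if thr <= 1e-6:
            return []
    mask = signal > thr
    labeled = measure.label(mask, connectivity=2)
    regions: list[tuple[BoundingBox, float]] = []
    for region in measure.regionprops(labeled):
        if region.area < config.min_area:
            continue
        y0, x0, y1, x1 = region.bbox
        box = BoundingBox(float(x0), float(y0), float(x1 - x0), float(y1 - y0))
        comp = signal[y0:y1, x0:x1]
        inside = labeled[y0:y1, x0:x1] == region.label
        peak = float(comp[inside].max())
        area = float(np.count_nonzero(inside & (comp >= 0.5 * peak)))
        regions.append((box, max(area, 1.0)))
    regions.sort(key=lambda rb: (rb[0].y_min, rb[0].x_min))
    return regions


def segment_slice(image: np.ndarray, config: DetectorConfig) -> list[BoundingBox]:
    """Threshold the flattened slice and return connected-component boxes
    with area >= ``min_area``. Deterministic; a (near-)constant image
    yields no boxes."""
    return [box for box, _ in _segment_regions(image, config)]


def focus_score(
    image: np.ndarray, bbox: BoundingBox, presmooth_sigma: float = 0.7
) -> float:
    """High-frequency energy inside the box; higher = sharper.

    Variance of the discrete Laplacian of the patch on the [0, 1]
    intensity scale, after a light Gaussian pre-smooth that suppresses
    per-pixel sensor noise (whose Laplacian variance would otherwise
    swamp the defocus signal). Invariant to constant intensity offsets;
    a constant patch scores 0. Defocus blur attenuates both the edge
    sharpness and, by absorbance conservation, the contrast, so the score
    decreases monotonically with distance from the focal plane.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    x0, y0 = int(np.floor(bbox.x_min)), int(np.floor(bbox.y_min))
    x1, y1 = int(np.ceil(bbox.x_max)), int(np.ceil(bbox.y_max))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x1 - x0 < 1 or y1 - y0 < 1:
        raise ValueError("degenerate box: no pixels inside the image")
    patch = image[y0:y1, x0:x1]
    if float(patch.var()) == 0.0:
        return 0.0
    if presmooth_sigma > 0:
        patch = ndimage.gaussian_filter(patch, presmooth_sigma)
    lap = ndimage.laplace(patch)
    return float(lap.var())


def _size_margin(n: float) -> float:
    """Confidence factor from the distance of the cell-equivalent estimate
    to the nearest class boundary (1.5 and 14.5 counts); bounded < 1."""
    boundaries = (1.5, COLONY_MIN_CELLS - 0.5)
    dist = min(abs(n - b) for b in boundaries)
    return min(0.95, 0.5 + 0.4 * min(dist, 1.0))


def classify_blob(
    area: float, focus: float, config: DetectorConfig
) -> tuple[str, float] | None:
    """Assign a class and confidence to a segmented blob.

    n = round(area / cell_area) cell-equivalents. In focus: n=1 -> cell,
    2-14 -> cluster, >= 15 -> colony. Out of focus: n >= 2 -> candidate (a
    larger object may come into focus elsewhere in the stack); n < 2 ->
    None (not a detection). The in-focus cut is ``focus_threshold``
    scaled down by n**0.25: the Laplacian energy of a blob concentrates
    at its rim, whose pixel share shrinks with size, so larger objects
    legitimately score lower at equal sharpness. Confidence is the
    product of a focus margin and a size margin, strictly below 1.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    config.validate()
    n_raw = area / config.cell_area
    n = max(1, round(n_raw))
    thr_eff = config.focus_threshold / max(n_raw, 1.0) ** 0.25
    focus_term = focus / (focus + thr_eff) if thr_eff > 0 else 0.99
    if focus >= thr_eff:
        if n == 1:
            label = CELL
        elif n < COLONY_MIN_CELLS:
            label = CLUSTER
        else:
            label = COLONY
        confidence = max(0.0, min(0.99, focus_term)) * _size_margin(n_raw)
    else:
        if n < 2:
            return None
        label = CANDIDATE
        confidence = max(0.0, min(0.99, 1.0 - focus_term)) * _size_margin(n_raw) * 0.5
    return label, float(min(confidence, 0.999))


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression by descending confidence.

    Surviving pairs have IoU < threshold; idempotent. Ties broken by
    box position for determinism.
    """
    ordered = sorted(
        detections,
        key=lambda d: (-d.confidence, d.bbox.y_min, d.bbox.x_min),
    )
    kept: list[Detection] = []
    for det in ordered:
        if all(iou(det.bbox, k.bbox) < iou_threshold for k in kept):
            kept.append(det)
    return kept


def detect_slice(
    image: np.ndarray, config: DetectorConfig, slice_index: int = -1
) -> list[Detection]:
    """Full per-slice pipeline: segment, focus-score, classify, filter by
    confidence, suppress duplicates."""
    detections: list[Detection] = []
    for box, area in _segment_regions(image, config):
        score = focus_score(image, box)
        result = classify_blob(area, score, config)
        if result is None:
            continue
        label, confidence = result
        if confidence < config.confidence_threshold or confidence >= 1.0:
            continue
        detections.append(Detection(box, label, confidence, slice_index))
    return nms(detections, config.nms_iou)


def detect_stack(
    stack: np.ndarray, config: DetectorConfig
) -> list[list[Detection]]:
    """Run the slice detector over a (n_slices, h, w) stack."""
    return [detect_slice(stack[i], config, slice_index=i) for i in range(stack.shape[0])]
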