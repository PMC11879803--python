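"""Readers and writers for the pipeline's exchange formats.

Dialects: image stacks as multi-page TIFF or zero-padded PNG slice
sequences; per-slice YOLO-style normalized box text; MOTChallenge-style
CSV trajectories (frames 1-based externally, converted to 0-based slice
indices internally — the conversion lives only here); tidy CSV results.
Round trips are lossless within the stated float precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .boxes import BoundingBox
from .classes import CLASS_NAMES, CLASS_ORDER
from .detect import Detection
from .synthgen import GroundTruth
from .ztrack import Track

__all__ = [
    "AnnotationRecord",
    "write_stack",
    "read_stack",
    "read_yolo_boxes",
    "write_yolo_boxes",
    "read_mot",
    "write_mot",
    "gt_to_records",
    "tracks_to_records",
    "records_to_frames",
    "detections_to_csv",
    "detections_from_csv",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated box: 0-based slice index, optional identity/confidence."""

    slice_index: int
    bbox: BoundingBox
    cls: str
    track_id: int = -1
    confidence: float = 1.0


# ---------------------------------------------------------------- stacks


def write_stack(stack: np.ndarray, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a float [0,1] stack as multi-page TIFF (path ending .tif[f])
    or a directory of zero-padded PNG slices."""
    path = Path(path)
    if bit_depth == 8:
        data = np.clip(np.round(stack * 255), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.clip(np.round(stack * 65535), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i in range(data.shape[0]):
            iio.imwrite(path / f"slice_{i:03d}.png", data[i])
    return path


def read_stack(path: str | Path) -> np.ndarray:
    """Read a stack written by :func:`write_stack` back to float [0,1]."""
    path = Path(path)
    if path.is_file():
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    else:
        files = sorted(path.glob("slice_*.png"))
        if not files:
            raise FileNotFoundError(f"no slice_*.png files under {path}")
        data = np.stack([iio.imread(f) for f in files])
    scale = 255.0 if data.dtype == np.uint8 else 65535.0
    return data.astype(np.float64) / scale


# ------------------------------------------------------------ YOLO boxes


def read_yolo_boxes(
    path: str | Path, image_size: tuple[int, int], slice_index: int = 0
) -> list[AnnotationRecord]:
    """Parse one slice's YOLO text: ``class_index x_center y_center width
    height``, all normalized to [0,1]; converts to pixel-space half-open
    boxes. Out-of-range values raise with the offending line number."""
    w, h = image_size
    records: list[AnnotationRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        cls_idx = int(parts[0])
        vals = [float(v) for v in parts[1:5]]
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"{path}:{lineno}: normalized values outside [0,1]")
        if not (0 <= cls_idx < len(CLASS_NAMES)):
            raise ValueError(f"{path}:{lineno}: class index {cls_idx} out of range")
        xc, yc, bw, bh = vals
        conf = float(parts[5]) if len(parts) == 6 else 1.0
        records.append(
            AnnotationRecord(
                slice_index=slice_index,
                bbox=BoundingBox((xc - bw / 2) * w, (yc - bh / 2) * h, bw * w, bh * h),
                cls=CLASS_NAMES[cls_idx],
                confidence=conf,
            )
        )
    return records


def write_yolo_boxes(
    records: list[AnnotationRecord],
    path: str | Path,
    image_size: tuple[int, int],
    with_confidence: bool = False,
) -> Path:
    """Write one slice's boxes in YOLO normalized format (6 decimals)."""
    w, h = image_size
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for r in records:
        cx, cy = r.bbox.center
        fields = [
            str(CLASS_ORDER[r.cls]),
            f"{cx / w:.6f}",
            f"{cy / h:.6f}",
            f"{r.bbox.width / w:.6f}",
            f"{r.bbox.height / h:.6f}",
        ]
        if with_confidence:
            fields.append(f"{r.confidence:.4f}")
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


# ------------------------------------------------------- MOTChallenge CSV


def write_mot(records: list[AnnotationRecord], path: str | Path) -> Path:
    """Write trajectories as MOTChallenge lines:
    ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,class,visibility``
    with frame = slice_index + 1 (1-based externally)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in sorted(records, key=lambda r: (r.slice_index, r.track_id)):
            writer.writerow(
                [
                    r.slice_index + 1,
                    r.track_id,
                    f"{r.bbox.x_min:.4f}",
                    f"{r.bbox.y_min:.4f}",
                    f"{r.bbox.width:.4f}",
                    f"{r.bbox.height:.4f}",
                    f"{r.confidence:.4f}",
                    CLASS_ORDER[r.cls],
                    -1,
                ]
            )
    return path


def read_mot(path: str | Path) -> dict[int, list[AnnotationRecord]]:
    """Read MOTChallenge lines into {track_id -> records sorted by slice}.

    Frames are converted to 0-based slice indices. Duplicate (frame, id)
    pairs are an error; non-monotone frames within an id are sorted.
    """
    tracks: dict[int, list[AnnotationRecord]] = {}
    seen: set[tuple[int, int]] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) < 7:
            raise ValueError(f"{path}:{lineno}: expected >= 7 fields")
        frame, track_id = int(parts[0]), int(parts[1])
        if (frame, track_id) in seen:
            raise ValueError(f"{path}:{lineno}: duplicate (frame, id) = ({frame}, {track_id})")
        seen.add((frame, track_id))
        cls_idx = int(parts[7]) if len(parts) > 7 and parts[7] not in ("", "-1") else None
        cls = CLASS_NAMES[cls_idx] if cls_idx is not None else CLASS_NAMES[0]
        tracks.setdefault(track_id, []).append(
            AnnotationRecord(
                slice_index=frame - 1,
                bbox=BoundingBox(
                    float(parts[2]), float(parts[3]), float(parts[4]), float(parts[5])
                ),
                cls=cls,
                track_id=track_id,
                confidence=float(parts[6]),
            )
        )
    for recs in tracks.values():
        recs.sort(key=lambda r: r.slice_index)
    return tracks


def gt_to_records(gt: GroundTruth) -> list[AnnotationRecord]:
    """Flatten synthetic ground truth for MOT/YOLO export (conf = 1)."""
    out = []
    for sl, entries in gt.entries.items():
        for e in entries:
            out.append(
                AnnotationRecord(
                    slice_index=sl, bbox=e.bbox, cls=e.label, track_id=e.object_id
                )
            )
    return out


def tracks_to_records(tracks: list[Track]) -> list[AnnotationRecord]:
    out = []
    for t in tracks:
        for sl, det in t.entries:
            out.append(
                AnnotationRecord(
                    slice_index=sl,
                    bbox=det.bbox,
                    cls=det.label,
                    track_id=t.track_id,
                    confidence=det.confidence,
                )
            )
    return out


def records_to_frames(
    tracks: dict[int, list[AnnotationRecord]],
) -> dict[int, dict[int, BoundingBox]]:
    """Track-shaped view for the evaluation module."""
    return {
        tid: {r.slice_index: r.bbox for r in recs} for tid, recs in tracks.items()
    }


# --------------------------------------------------------- detections CSV


def detections_to_csv(detections: list[Detection], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "slice_index": d.slice_index,
            "label": d.label,
            "confidence": round(d.confidence, 4),
            "x_min": d.bbox.x_min,
            "y_min": d.bbox.y_min,
            "width": d.bbox.width,
            "height": d.bbox.height,
        }
        for d in detections
    ]
    pd.DataFrame(
        rows,
        columns=["slice_index", "label", "confidence", "x_min", "y_min", "width", "height"],
    ).to_csv(path, index=False)
    return path


def detections_from_csv(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(
            bbox=BoundingBox(r.x_min, r.y_min, r.width, r.height),
            label=r.label,
            confidence=float(r.confidence),
            slice_index=int(r.slice_index),
        )
        for r in df.itertuples()
    ]
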