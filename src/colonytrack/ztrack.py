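"""Merge per-slice detections along Z into unique 2.5D objects.

Multi-object tracking is reformulated from the temporal to the axial
domain: the "frames" are Z-slices, and a trajectory is one physical
object seen across focal planes. Association is two-stage IoU matching in
the spirit of ByteTrack/BoT-SORT — high-confidence detections are matched
first by globally optimal assignment on 1 - IoU, then remaining tracks
get a second chance against low-confidence detections — with gap
tolerance so an object that drops out of focus for a few slices is
re-identified rather than duplicated.

Appearance embeddings and camera-motion compensation are deliberately
absent: Z-stack scenes are quasi-static, so the predicted box is simply
the last observed box (a motion-model hook is provided for anything
smarter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import BoundingBox, iou, iou_matrix
from .classes import max_class
from .detect import Detection

__all__ = ["Track", "TrackerConfig", "iou", "associate", "track_stack", "classify_track"]

TENTATIVE = "tentative"
ACTIVE = "active"
LOST = "lost"
FINISHED = "finished"


@dataclass
class Track:
    """An ordered chain of detections across slices with one identity."""

    track_id: int
    entries: list[tuple[int, Detection]] = field(default_factory=list)
    state: str = TENTATIVE
    gap_count: int = 0

    def add(self, slice_index: int, detection: Detection) -> None:
        if self.entries and slice_index <= self.entries[-1][0]:
            raise ValueError("slice indices within a track must strictly increase")
        self.entries.append((slice_index, detection))

    @property
    def last_box(self) -> BoundingBox:
        return self.entries[-1][1].bbox

    @property
    def labels(self) -> list[str]:
        return [d.label for _, d in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frames(self) -> dict[int, BoundingBox]:
        return {sl: det.bbox for sl, det in self.entries}


@dataclass(frozen=True)
class TrackerConfig:
    """Two-stage association thresholds and track lifecycle parameters.

    ``max_gap`` is how many consecutive slices a track may go unmatched
    before it is finished; within the gap it stays eligible for
    re-association. Tracks shorter than ``min_length`` are discarded at
    the end. Defaults are exposed configuration, searched jointly with
    the detector's by the tuning harness.
    """

    high_conf: float = 0.4
    low_conf: float = 0.1
    match_iou_high: float = 0.3
    match_iou_low: float = 0.2
    max_gap: int = 3
    min_length: int = 1

    def validate(self) -> None:
        if not (0.0 <= self.low_conf <= self.high_conf <= 1.0):
            raise ValueError("require 0 <= low_conf <= high_conf <= 1")
        for name in ("match_iou_high", "match_iou_low"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.max_gap < 0 or self.min_length < 1:
            raise ValueError("max_gap >= 0 and min_length >= 1 required")


def _match_stage(
    track_boxes: list[BoundingBox],
    det_boxes: list[BoundingBox],
    iou_min: float,
) -> list[tuple[int, int]]:
    """Globally cost-optimal assignment on cost 1 - IoU, keeping only
    pairs with IoU >= iou_min. Hungarian assignment is deterministic;
    equal-cost ties resolve to the lowest index pair."""
    if not track_boxes or not det_boxes:
        return []
    overlap = iou_matrix(track_boxes, det_boxes)
    rows, cols = linear_sum_assignment(1.0 - overlap)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if overlap[r, c] >= iou_min]


def associate(
    tracks: Sequence[Track],
    detections: Sequence[Detection],
    config: TrackerConfig,
    predict: Callable[[Track], BoundingBox] | None = None,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Two-stage IoU association of one slice's detections to tracks.

    Returns (matches, unmatched_track_indices, unmatched_detection_indices)
    as indices into the input sequences. Stage 1 assigns detections with
    confidence >= high_conf at IoU >= match_iou_high; stage 2 assigns
    leftover tracks to detections with low_conf <= confidence < high_conf
    at IoU >= match_iou_low. Each stage is a globally minimum-cost
    assignment. Detections below low_conf are ignored.
    """
    config.validate()
    slices = {d.slice_index for d in detections}
    if len(slices) > 1:
        raise ValueError(f"detections span multiple slices: {sorted(slices)}")
    predict = predict or (lambda t: t.last_box)
    track_boxes = [predict(t) for t in tracks]

    high = [i for i, d in enumerate(detections) if d.confidence >= config.high_conf]
    low = [
        i
        for i, d in enumerate(detections)
        if config.low_conf <= d.confidence < config.high_conf
    ]

    matches: list[tuple[int, int]] = []
    matched_tracks: set[int] = set()
    matched_dets: set[int] = set()

    stage1 = _match_stage(
        track_boxes, [detections[i].bbox for i in high], config.match_iou_high
    )
    for r, c in stage1:
        matches.append((r, high[c]))
        matched_tracks.add(r)
        matched_dets.add(high[c])

    rem_tracks = [i for i in range(len(tracks)) if i not in matched_tracks]
    stage2 = _match_stage(
        [track_boxes[i] for i in rem_tracks],
        [detections[i].bbox for i in low],
        config.match_iou_low,
    )
    for r, c in stage2:
        matches.append((rem_tracks[r], low[c]))
        matched_tracks.add(rem_tracks[r])
        matched_dets.add(low[c])

    unmatched_tracks = [i for i in range(len(tracks)) if i not in matched_tracks]
    unmatched_dets = [i for i in range(len(detections)) if i not in matched_dets]
    matches.sort()
    return matches, unmatched_tracks, unmatched_dets


def track_stack(
    detections_by_slice: Sequence[Sequence[Detection]],
    config: TrackerConfig,
    predict: Callable[[Track], BoundingBox] | None = None,
) -> list[Track]:
    """Run the tracker over an ordered stack of per-slice detections.

    Matched tracks extend and reset their gap counter; unmatched tracks
    accumulate gaps and finish once gap_count > max_gap (staying eligible
    for re-association until then); unmatched detections of at least
    high confidence seed new tracks. Track ids are unique and never
    reused. Tracks shorter than ``min_length`` are dropped from the
    output. Output order and ids are invariant to permutations of the
    detections within a slice (deterministic tie-breaking).
    """
    config.validate()
    next_id = 0
    live: list[Track] = []
    done: list[Track] = []

    for slice_index, dets in enumerate(detections_by_slice):
        # canonical in-slice order for permutation-invariant ids
        dets = sorted(
            dets,
            key=lambda d: (-d.confidence, d.bbox.y_min, d.bbox.x_min, d.bbox.width),
        )
        matches, unmatched_tracks, unmatched_dets = associate(
            live, dets, config, predict
        )
        for ti, di in matches:
            live[ti].add(slice_index, dets[di])
            live[ti].gap_count = 0
            live[ti].state = ACTIVE
        for ti in unmatched_tracks:
            live[ti].gap_count += 1
            live[ti].state = LOST
        for di in unmatched_dets:
            if dets[di].confidence >= config.high_conf:
                t = Track(track_id=next_id, state=TENTATIVE)
                next_id += 1
                t.add(slice_index, dets[di])
                live.append(t)
        still_live: list[Track] = []
        for t in live:
            if t.gap_count > config.max_gap:
                t.state = FINISHED
                done.append(t)
            else:
                still_live.append(t)
        live = still_live

    for t in live:
        t.state = FINISHED
        done.append(t)
    done = [t for t in done if len(t) >= config.min_length]
    done.sort(key=lambda t: t.track_id)
    return done


def classify_track(track: Track) -> str:
    """Final hierarchical class: maximum of the per-slice labels under
    candidate < cell < cluster < colony. A trajectory that was only ever
    seen out of focus stays a candidate."""
    if not track.entries:
        raise ValueError("cannot classify an empty track")
    return max_class(track.labels)
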